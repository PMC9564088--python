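"""Relapse vs non-relapse cohort comparisons: Welch t-tests and ROC cut-offs.

Scores are normalized diversity indices (or their TP2->TP3 increase, delta
SDI).  The ROC positive class defaults to the non-relapse group, because
diversity recovers faster in patients who cleared their tumor: with an
SDI-type score the reported AUC is then >= 0.5 whenever that direction holds.
The dichotomous cut-off maximizes the Youden index J = sensitivity +
specificity - 1, with deterministic tie-breaks (highest sensitivity, then
lowest threshold), and is reported as the midpoint between the adjacent
distinct scores it separates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .diversity import (
    INDICES,
    LEVELS,
    TrajectoryRecord,
    delta_sdi,
    diversity_profile,
    normalize_to_healthy,
)
from .exceptions import DegenerateDataError, ValidationError
from .io import CohortRecord, Repertoire
from .network import build_network

__all__ = [
    "GroupComparison",
    "compare_groups",
    "ROCResult",
    "roc_analysis",
    "CohortReport",
    "cohort_pipeline",
    "TIMEPOINTS",
]

TIMEPOINTS = ("TP1", "TP2", "TP3", "TP4")


@dataclass
class GroupComparison:
    """Welch's unequal-variance t-test between two groups."""

    mean_a: float
    mean_b: float
    var_a: float
    var_b: float
    n_a: int
    n_b: int
    t_statistic: float
    df: float
    p_value: float


def compare_groups(a, b) -> GroupComparison:
    """Welch t statistic with Welch-Satterthwaite degrees of freedom and a
    two-sided p-value.  Both groups need n >= 2 and nonzero variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 or vb == 0:
        raise DegenerateDataError(
            "zero within-group variance; report exact equality instead of a t-test"
        )
    res = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / a.size, vb / b.size
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    return GroupComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        var_a=float(va),
        var_b=float(vb),
        n_a=int(a.size),
        n_b=int(b.size),
        t_statistic=float(res.statistic),
        df=float(df),
        p_value=float(res.pvalue),
    )


@dataclass
class ROCResult:
    """Empirical ROC curve with Youden-optimal cut-off."""

    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    curve: list[tuple[float, float]] = field(default_factory=list)  # (FPR, TPR)
    n_positive: int = 0
    n_negative: int = 0


def roc_analysis(scores, labels, positive: str = "non_relapse") -> ROCResult:
    """Empirical ROC of ``scores`` against binary ``labels``.

    A sample is called positive when its score is >= the threshold.  The AUC
    is the trapezoidal area under the empirical curve, which equals the
    rank statistic P(score_pos > score_neg) + 0.5 P(equal).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if lab == positive else 0 for lab in labels])
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DegenerateDataError("ROC requires both classes present")

    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = y[order]

    # Curve points at every distinct threshold, descending: each point is the
    # (FPR, TPR) after classifying all scores >= that threshold as positive.
    fprs = [0.0]
    tprs = [0.0]
    thresholds: list[float] = []  # threshold generating each interior point
    tp = fp = 0
    i = 0
    while i < y_sorted.size:
        j = i
        while j < y_sorted.size and s_sorted[j] == s_sorted[i]:
            tp += y_sorted[j]
            fp += 1 - y_sorted[j]
            j += 1
        fprs.append(fp / n_neg)
        tprs.append(tp / n_pos)
        thresholds.append(float(s_sorted[i]))
        i = j
    auc = float(np.trapezoid(tprs, fprs))

    # Youden-optimal threshold among distinct observed scores; ties -> highest
    # sensitivity, then lowest threshold.
    best = None
    for k, thr in enumerate(thresholds):
        sens = tprs[k + 1]
        spec = 1.0 - fprs[k + 1]
        j_stat = sens + spec - 1.0
        key = (j_stat, sens, -thr)
        if best is None or key > best[0]:
            best = (key, thr, sens, spec, k)
    _, thr, sens, spec, k = best
    # A sample is positive when score >= threshold, so the decision boundary
    # separates the chosen score from the next lower distinct score; report
    # their midpoint (the threshold itself if it is the minimum score).
    lower = thresholds[k + 1] if k + 1 < len(thresholds) else thr
    cutoff = (thr + lower) / 2.0
    return ROCResult(
        auc=auc,
        cutoff=float(cutoff),
        sensitivity=float(sens),
        specificity=float(spec),
        curve=list(zip(fprs, tprs)),
        n_positive=n_pos,
        n_negative=n_neg,
    )


@dataclass
class CohortReport:
    """Consolidated cohort analysis output.

    ``profiles`` holds every normalized per-sample DiversityProfile;
    ``trajectories`` one record per patient (vertex-level normalized SDI);
    ``roc`` maps (measure, level, timepoint-or-'delta_sdi') to ROCResult;
    ``comparisons`` the matching Welch tests where both groups have n >= 2.
    """

    profiles: list = field(default_factory=list)
    trajectories: list[TrajectoryRecord] = field(default_factory=list)
    roc: dict[tuple[str, str, str], ROCResult] = field(default_factory=dict)
    comparisons: dict[tuple[str, str, str], GroupComparison] = field(default_factory=dict)

    def trajectory_frame(self):
        import pandas as pd

        rows = []
        for p in self.profiles:
            rows.append(
                {
                    "sample_id": p.sample_id,
                    "level": p.level,
                    "richness": p.richness,
                    "shannon": p.shannon,
                    "gini_simpson": p.gini_simpson,
                    "gini": p.gini,
                    "normalized_shannon": p.normalized_shannon,
                    "normalized_gini_simpson": p.normalized_gini_simpson,
                    "normalized_gini": p.normalized_gini,
                }
            )
        return pd.DataFrame(rows)

    def roc_frame(self):
        import pandas as pd

        rows = [
            {
                "measure": m,
                "level": lv,
                "timepoint": tp,
                "auc": r.auc,
                "cutoff": r.cutoff,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "n_positive": r.n_positive,
                "n_negative": r.n_negative,
            }
            for (m, lv, tp), r in sorted(self.roc.items())
        ]
        return pd.DataFrame(rows)


def cohort_pipeline(
    cohort: list[CohortRecord],
    repertoires: dict[tuple[str, str], Repertoire],
    healthy: list[Repertoire],
    neighbor_rule: str = "hamming1",
    base: float | None = None,
) -> CohortReport:
    """Full patient-cohort diversity analysis.

    Parameters
    ----------
    cohort
        Patient records with relapse (progression) labels.
    repertoires
        Keyed by (patient_no, timepoint), timepoints in TP1..TP4.
    healthy
        Healthy-volunteer repertoires defining the normalization baseline.

    Computes vertex- and cluster-level indices for every sample, normalizes
    to the healthy means, assembles per-patient normalized-SDI trajectories
    with delta SDI (TP3 - TP2), and runs ROC (positive class non_relapse)
    plus Welch tests for every measure at every timepoint where both groups
    are represented, and for delta SDI.  Patients missing TP2 or TP3 are
    excluded from the delta-SDI analyses with a warning.
    """
    if not healthy:
        raise DegenerateDataError("healthy cohort is empty; normalization impossible")

    def profiles_of(rep: Repertoire):
        net = build_network(rep, neighbor_rule=neighbor_rule)
        return [diversity_profile(rep, net, level=lv, base=base) for lv in LEVELS]

    healthy_profiles = []
    for rep in healthy:
        healthy_profiles.extend(profiles_of(rep))

    sample_profiles: dict[tuple[str, str, str], object] = {}
    flat = []
    keys = []
    for (pid, tp), rep in sorted(repertoires.items()):
        for prof in profiles_of(rep):
            flat.append(prof)
            keys.append((pid, tp, prof.level))
    flat = normalize_to_healthy(flat, healthy_profiles)
    for key, prof in zip(keys, flat):
        sample_profiles[key] = prof

    label_of = {r.patient_no: ("relapse" if r.progression else "non_relapse") for r in cohort}

    trajectories = []
    for rec in cohort:
        sdi = {
            tp: sample_profiles[(rec.patient_no, tp, "vertex")].normalized_shannon
            for tp in TIMEPOINTS
            if (rec.patient_no, tp, "vertex") in sample_profiles
        }
        d = delta_sdi(sdi)
        if d is None:
            warnings.warn(
                f"patient {rec.patient_no}: missing TP2 or TP3; excluded from delta-SDI analyses",
                stacklevel=2,
            )
        trajectories.append(TrajectoryRecord(subject_id=rec.patient_no, normalized_sdi=sdi, delta_sdi=d))

    roc: dict[tuple[str, str, str], ROCResult] = {}
    comparisons: dict[tuple[str, str, str], GroupComparison] = {}

    def analyze(measure, level, tp, scores, labels):
        if len(set(labels)) < 2:
            return
        roc[(measure, level, tp)] = roc_analysis(scores, labels)
        non = [s for s, lab in zip(scores, labels) if lab == "non_relapse"]
        rel = [s for s, lab in zip(scores, labels) if lab == "relapse"]
        if len(non) >= 2 and len(rel) >= 2:
            try:
                comparisons[(measure, level, tp)] = compare_groups(non, rel)
            except DegenerateDataError:
                pass

    for measure in INDICES:
        for level in LEVELS:
            for tp in TIMEPOINTS:
                scores, labels = [], []
                for rec in cohort:
                    prof = sample_profiles.get((rec.patient_no, tp, level))
                    if prof is not None:
                        scores.append(prof.value(measure, normalized=True))
                        labels.append(label_of[rec.patient_no])
                if scores:
                    analyze(measure, level, tp, scores, labels)

    d_scores = [t.delta_sdi for t in trajectories if t.delta_sdi is not None]
    d_labels = [label_of[t.subject_id] for t in trajectories if t.delta_sdi is not None]
    if d_scores:
        analyze("shannon", "vertex", "delta_sdi", d_scores, d_labels)

    return CohortReport(
        profiles=flat,
        trajectories=trajectories,
        roc=roc,
        comparisons=comparisons,
    )
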
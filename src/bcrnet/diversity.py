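"""Clonal diversity indices and healthy-cohort normalization.

Three indices of clone-frequency structure are computed, at two levels of
aggregation (individual vertices = unique CDR3 sequences, or clusters =
network clones):

Shannon diversity index (SDI)
    H = -sum_i p_i ln p_i, in nats by default (a ``base`` argument is
    provided for comparability with log2/log10 conventions).
Gini-Simpson coefficient
    D = 1 - sum_i p_i^2, the probability that two reads drawn at random come
    from different clones.
Gini index
    G = sum_{i,j} |x_i - x_j| / (2 n^2 xbar), inequality of clone sizes
    (0 = perfectly even).

Patient indices are normalized by dividing by the corresponding arithmetic
mean over a healthy-volunteer cohort, computed index-by-index and
level-by-level; the normalized SDI trajectory and its TP2->TP3 increase
(delta SDI) are the downstream relapse discriminators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError, EmptyRepertoireError, ValidationError
from .io import Repertoire
from .network import ClonalNetwork, cluster_abundances

__all__ = [
    "shannon",
    "gini_simpson",
    "gini",
    "DiversityProfile",
    "diversity_profile",
    "normalize_to_healthy",
    "TrajectoryRecord",
    "delta_sdi",
    "v_gene_usage",
    "rarefy",
]

INDICES = ("shannon", "gini_simpson", "gini")
LEVELS = ("vertex", "cluster")


def _as_probs(counts) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    if x.size == 0:
        raise EmptyRepertoireError("diversity of an empty count vector is undefined")
    if np.any(x <= 0):
        raise ValidationError("counts must all be positive")
    return x / x.sum()


def shannon(counts, base: float | None = None) -> float:
    """Shannon diversity index H = -sum p_i log p_i (nats unless ``base``)."""
    p = _as_probs(counts)
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return max(h, 0.0)


def gini_simpson(counts) -> float:
    """Gini-Simpson coefficient D = 1 - sum p_i^2."""
    p = _as_probs(counts)
    return float(1.0 - (p * p).sum())


def gini(counts) -> float:
    """Gini index of clone-size inequality, G = sum|x_i - x_j| / (2 n^2 xbar).

    Computed via the sorted-rank identity, O(n log n), exactly equal to the
    pairwise-difference definition.
    """
    x = np.asarray(counts, dtype=float)
    if x.size == 0:
        raise EmptyRepertoireError("gini of an empty count vector is undefined")
    if np.any(x <= 0):
        raise ValidationError("counts must all be positive")
    x = np.sort(x)
    n = x.size
    ranks = np.arange(1, n + 1)
    return float(((2 * ranks - n - 1) * x).sum() / (n * n * x.mean()))


@dataclass
class DiversityProfile:
    """Richness plus the three indices for one sample at one level."""

    sample_id: str
    level: str  # vertex | cluster
    richness: int
    shannon: float
    gini_simpson: float
    gini: float
    total_reads: int
    normalized_shannon: float | None = None
    normalized_gini_simpson: float | None = None
    normalized_gini: float | None = None

    def value(self, index: str, normalized: bool = False) -> float | None:
        return getattr(self, f"normalized_{index}" if normalized else index)


def diversity_profile(
    repertoire: Repertoire,
    network: ClonalNetwork,
    level: str = "vertex",
    base: float | None = None,
) -> DiversityProfile:
    """Diversity indices of a repertoire at vertex or cluster level.

    The network must have been built from the same repertoire; vertex level
    uses per-vertex aggregated read counts, cluster level the per-cluster
    aggregate counts.
    """
    if level not in LEVELS:
        raise ValidationError(f"level must be one of {LEVELS}")
    if network.n_vertices == 0:
        raise EmptyRepertoireError(f"{repertoire.sample_id}: empty network has no diversity profile")
    counts = network.counts if level == "vertex" else cluster_abundances(network)
    return DiversityProfile(
        sample_id=repertoire.sample_id,
        level=level,
        richness=len(counts),
        shannon=shannon(counts, base=base),
        gini_simpson=gini_simpson(counts),
        gini=gini(counts),
        total_reads=int(sum(counts)),
    )


def normalize_to_healthy(
    profiles: list[DiversityProfile], healthy: list[DiversityProfile]
) -> list[DiversityProfile]:
    """Divide each index by the healthy-cohort arithmetic mean, per level.

    Returns new profiles with the ``normalized_*`` fields populated. Healthy
    profiles must include every level present among ``profiles``.
    """
    if not healthy:
        raise DegenerateDataError("healthy cohort is empty; normalization impossible")
    means: dict[tuple[str, str], float] = {}
    for level in {p.level for p in profiles}:
        ref = [h for h in healthy if h.level == level]
        if not ref:
            raise DegenerateDataError(f"no healthy profiles at level {level!r}")
        for index in INDICES:
            m = float(np.mean([h.value(index) for h in ref]))
            if m == 0.0:
                raise DegenerateDataError(f"healthy mean of {index} at {level!r} level is zero")
            means[(level, index)] = m
    out = []
    for p in profiles:
        out.append(
            replace(
                p,
                **{
                    f"normalized_{index}": p.value(index) / means[(p.level, index)]
                    for index in INDICES
                },
            )
        )
    return out


@dataclass
class TrajectoryRecord:
    """Per-subject normalized SDI across treatment timepoints.

    ``delta_sdi`` is normalized SDI(TP3) - normalized SDI(TP2): the recovery
    of repertoire diversity over the 6-8 weeks after stem cell rescue.  It is
    ``None`` (missing-data marker) when either timepoint is absent.
    """

    subject_id: str
    normalized_sdi: dict[str, float]
    delta_sdi: float | None = None


def delta_sdi(normalized_sdi_by_timepoint: dict[str, float]) -> float | None:
    """TP3 - TP2 on normalized SDI; ``None`` if either timepoint is missing."""
    tp2 = normalized_sdi_by_timepoint.get("TP2")
    tp3 = normalized_sdi_by_timepoint.get("TP3")
    if tp2 is None or tp3 is None:
        return None
    return tp3 - tp2


def v_gene_usage(repertoire: Repertoire, reference_pool: set[str]) -> pd.DataFrame:
    """Per-V-gene read fractions with abnormal flags.

    A V gene is *abnormal* when absent from ``reference_pool`` (typically the
    union of V genes seen in the healthy cohort); relapsed patients tend to
    carry more abnormal germline V gene usage.
    """
    usage: dict[str, int] = {}
    for c in repertoire.clonotypes:
        gene = c.v_gene or "unknown"
        usage[gene] = usage.get(gene, 0) + c.read_count
    total = sum(usage.values())
    rows = [
        {
            "v_gene": gene,
            "reads": n,
            "fraction": n / total,
            "abnormal": gene not in reference_pool,
        }
        for gene, n in sorted(usage.items())
    ]
    df = pd.DataFrame(rows)
    df.attrs["n_abnormal"] = int(df["abnormal"].sum()) if len(df) else 0
    return df


def rarefy(counts, depth: int, seed: int = 0):
    """Multinomial downsampling of a count vector to a common read depth.

    With ``depth`` equal to the total, returns the original counts unchanged.
    Zero categories after downsampling are dropped.  Off by default in all
    pipelines; provided for cross-depth comparability checks.
    """
    x = np.asarray(counts, dtype=int)
    total = int(x.sum())
    if depth > total:
        raise ValidationError(f"rarefaction depth {depth} exceeds total reads {total}")
    if depth == total:
        return x.copy()
    rng = np.random.default_rng(seed)
    sampled = rng.multinomial(depth, x / total)
    return sampled[sampled > 0]
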
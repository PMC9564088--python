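"""Synthetic repertoire generators.

Two generators provide the inputs the analysis modules expect:

``simulate_coculture``
    An in-vitro germinal-center (GC) culture of naive B cells on a feeder
    layer, with an optional co-seeded tumor compartment.  Growth is two-phase
    (slow IL-4-only priming for the first 4 days, fast expansion thereafter,
    slowing after day 14); somatic hypermutation (SHM) emits single-point-
    mutation daughters from day 4 during a maturation window, so the clonal
    network grows by Hamming-1 edges; cultures are replated to 1e5 cells at
    day 8 and every 4 days after, preserving clone proportions.  The tumor
    compartment grows faster, emits no BCR reads by default (mirroring a
    lymphoma line without stable BCR expression), and suppresses both normal
    growth and SHM through a saturating function of its population fraction;
    because suppression also slows GC maturation, the SHM window stretches
    and peak diversity arrives later than in a pure culture.

``simulate_patient_cohort``
    Peripheral repertoires for a transplant cohort at four timepoints (TP1
    suppressed, TP2 near-ablated at very low read depth, TP3 recovering at a
    rate reduced in patients who later relapse, TP4 relapse only), plus a
    healthy-volunteer cohort for normalization.  Relapse patients carry a
    planted monoclonal tumor clone from TP1 onward and receive a matching
    tumor signature, so the full pipeline can be checked by plant-and-recover.

All generators are bit-reproducible given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Clonotype, CohortRecord, Repertoire
from .tracking import TumorSignature, extract_primary_clusters

__all__ = [
    "mutate_sequence",
    "random_cdr3",
    "CocultureConfig",
    "CocultureResult",
    "simulate_coculture",
    "simulate_healthy_cohort",
    "PatientCohortConfig",
    "SyntheticCohort",
    "simulate_patient_cohort",
]

_BASES = np.array(list("ACGT"))


def random_cdr3(rng: np.random.Generator, length_range: tuple[int, int] = (27, 45)) -> str:
    """A uniform-random nucleotide string with length uniform in ``length_range``."""
    length = int(rng.integers(length_range[0], length_range[1] + 1))
    return "".join(rng.choice(_BASES, size=length))

def mutate_sequence(seq: str, rng: np.random.Generator) -> str:
    """Single point mutation: uniform position, uniform non-identical base.

    The result is always at Hamming distance exactly 1 from the input.
    """
    pos = int(rng.integers(len(seq)))
    old = seq[pos]
    choices = [b for b in "ACGT" if b != old]
    new = choices[int(rng.integers(3))]
    return seq[:pos] + new + seq[pos + 1 :]


@dataclass
class CocultureConfig:
    """Parameters of the GC / tumor co-culture simulator.

    Growth factors are per day.  The default schedule (1.2/day for days 0-4,
    2.0/day for days 4-14) yields a cumulative fold-expansion of
    1.2^4 * 2^10 ~ 2123 by day 14.  ``tumor_seed`` is the number of tumor
    cells co-seeded per 1e5 naive B cells, so the day-0 tumor fraction is
    tumor_seed / (1e5 + tumor_seed).  Suppression multiplies the normal
    growth increment and the SHM rate by (1 - s_max * f_T / (f_T + K)) where
    f_T is the tumor population fraction; with K = 1e-5 even a 0.001% seed
    produces a large effect.  SHM is active from day 4 until accumulated
    maturation (which advances at the suppressed rate) reaches
    ``shm_window``, so an unsuppressed culture stops diversifying at day 12.
    """

    n_naive_clones: int = 2000
    naive_clone_mean_size: float = 3.0  # geometric clone-size law (reads)
    cdr3_length_range: tuple[int, int] = (27, 45)
    initial_cells: float = 1e5
    growth_phase1: float = 1.2  # days 0-4, IL-4 only
    growth_phase2: float = 2.0  # days 4-14, IL-4 + IL-21
    growth_late: float = 1.1  # after day 14
    shm_rate: float = 0.02  # per cell per day, active from day 4
    shm_start: int = 4
    shm_window: float = 8.0  # maturation units of SHM activity
    replate_start: int = 8
    replate_every: int = 4
    replate_size: float = 1e5
    tumor_seed: int = 0  # tumor cells per 1e5 naive cells
    tumor_growth: float = 2.52  # calibrated: tumor fraction rises ~200-fold by day 14
    s_max: float = 0.5
    K: float = 1e-5
    tumor_emits_bcr: bool = False
    mode: str = "mean_field"  # mean_field | stochastic
    days: int = 19
    sample_days: tuple[int, ...] = (0, 8, 10, 12, 14, 19)
    sample_depth: int = 20000
    spawn_min: float = 0.5  # mean-field: minimum daughter mass to create a vertex
    prune_min: float = 1e-3  # mean-field: drop clones below this mass at replating
    seed: int = 0


@dataclass
class DayRecord:
    day: int
    n_normal: float
    n_tumor: float
    tumor_fraction: float
    cumulative_fold: float
    sdi: float
    richness: int


@dataclass
class CocultureResult:
    config: CocultureConfig
    days: list[DayRecord]
    repertoires: dict[int, Repertoire]

    def day_record(self, day: int) -> DayRecord:
        return next(r for r in self.days if r.day == day)

    def sdi_by_day(self) -> dict[int, float]:
        return {r.day: r.sdi for r in self.days}

    def day_of_max_sdi(self, through: int | None = None) -> int:
        """First day attaining the maximum SDI (optionally up to ``through``)."""
        recs = [r for r in self.days if through is None or r.day <= through]
        best = max(r.sdi for r in recs)
        return next(r.day for r in recs if r.sdi == best)


def _entropy(masses: np.ndarray) -> float:
    m = masses[masses > 0]
    if m.size == 0:
        return 0.0
    p = m / m.sum()
    return float(-(p * np.log(p)).sum())


def _growth_factor(cfg: CocultureConfig, t: int) -> float:
    if t < 4:
        return cfg.growth_phase1
    if t < 14:
        return cfg.growth_phase2
    return cfg.growth_late


def simulate_coculture(config: CocultureConfig | None = None, **overrides) -> CocultureResult:
    """Run the GC / tumor co-culture model and sample repertoires.

    Keyword overrides are applied on top of ``config`` (or the defaults), so
    ``simulate_coculture(tumor_seed=100, mode="stochastic", seed=3)`` works.
    """
    cfg = config or CocultureConfig()
    if overrides:
        from dataclasses import replace

        cfg = replace(cfg, **overrides)
    if cfg.mode not in ("mean_field", "stochastic"):
        raise ValueError(f"unknown mode {cfg.mode!r}")
    stochastic = cfg.mode == "stochastic"
    rng = np.random.default_rng(cfg.seed)
    sample_rng = np.random.default_rng(rng.integers(2**31))

    # Founder clones: geometric sizes (mean naive_clone_mean_size) used as
    # weights; the population is normalized to exactly `initial_cells`.
    seqs = [random_cdr3(rng, cfg.cdr3_length_range) for _ in range(cfg.n_naive_clones)]
    weights = rng.geometric(1.0 / cfg.naive_clone_mean_size, size=cfg.n_naive_clones).astype(float)
    if stochastic:
        masses = rng.multinomial(int(cfg.initial_cells), weights / weights.sum()).astype(float)
    else:
        masses = weights * (cfg.initial_cells / weights.sum())
    index = {s: i for i, s in enumerate(seqs)}
    tumor = float(cfg.tumor_seed)

    replate_days = set(range(cfg.replate_start, cfg.days + 1, cfg.replate_every))
    cumulative_fold = 1.0
    maturity = 0.0
    records: list[DayRecord] = []
    repertoires: dict[int, Repertoire] = {}

    def snapshot(day: int):
        n = float(masses.sum())
        records.append(
            DayRecord(
                day=day,
                n_normal=n,
                n_tumor=tumor,
                tumor_fraction=tumor / (n + tumor) if n + tumor > 0 else 0.0,
                cumulative_fold=cumulative_fold,
                sdi=_entropy(masses),
                richness=int((masses > 0).sum()),
            )
        )
        if day in cfg.sample_days:
            repertoires[day] = _sample_repertoire(
                seqs, masses, cfg.sample_depth, sample_rng, sample_id=f"DIV{day}", day=day
            )

    snapshot(0)
    for t in range(cfg.days):
        n = float(masses.sum())
        f_t = tumor / (n + tumor) if n + tumor > 0 else 0.0
        supp = 1.0 - cfg.s_max * f_t / (f_t + cfg.K) if tumor > 0 else 1.0
        g = _growth_factor(cfg, t)
        g_eff = 1.0 + (g - 1.0) * supp
        cumulative_fold *= g_eff

        if stochastic:
            masses = rng.poisson(masses * g_eff).astype(float)
            tumor = float(rng.poisson(tumor * cfg.tumor_growth))
        else:
            masses = masses * g_eff
            tumor *= cfg.tumor_growth

        shm_active = t >= cfg.shm_start and maturity < cfg.shm_window
        if shm_active:
            mu_eff = cfg.shm_rate * supp
            new_seqs: list[str] = []
            new_masses: list[float] = []
            if stochastic:
                mutants = rng.binomial(masses.astype(np.int64), mu_eff)
                donors = np.nonzero(mutants)[0]
                gains: dict[str, float] = {}
                for i in donors:
                    masses[i] -= mutants[i]
                    for _ in range(int(mutants[i])):
                        s = mutate_sequence(seqs[i], rng)
                        gains[s] = gains.get(s, 0.0) + 1.0
                for s, m in gains.items():
                    j = index.get(s)
                    if j is None:
                        index[s] = len(seqs)
                        new_seqs.append(s)
                        new_masses.append(m)
                    else:
                        masses[j] += m
            else:
                mutant_mass = masses * mu_eff
                donors = np.nonzero(mutant_mass >= cfg.spawn_min)[0]
                for i in donors:
                    m = mutant_mass[i]
                    masses[i] -= m
                    # favor a previously unseen daughter so each SHM event
                    # creates a new vertex adjacent to its parent
                    for _ in range(10):
                        s = mutate_sequence(seqs[i], rng)
                        if s not in index:
                            break
                    j = index.get(s)
                    if j is None:
                        index[s] = len(seqs)
                        new_seqs.append(s)
                        new_masses.append(m)
                    else:
                        masses[j] += m
            if new_seqs:
                seqs.extend(new_seqs)
                masses = np.concatenate([masses, np.asarray(new_masses)])
        if t >= cfg.shm_start:
            maturity += supp

        day = t + 1
        if day in replate_days:
            total = masses.sum() + tumor
            if total > cfg.replate_size:
                scale = cfg.replate_size / total
                if stochastic:
                    keep = rng.multinomial(
                        int(round(tumor * scale + masses.sum() * scale)),
                        np.concatenate([masses, [tumor]]) / total,
                    )
                    masses = keep[:-1].astype(float)
                    tumor = float(keep[-1])
                else:
                    masses = masses * scale
                    tumor *= scale
            # drop extinct / negligible clones, keep index consistent
            thresh = 0.5 if stochastic else cfg.prune_min
            alive = masses >= thresh
            seqs = [s for s, a in zip(seqs, alive) if a]
            masses = masses[alive]
            index = {s: i for i, s in enumerate(seqs)}
        snapshot(day)

    return CocultureResult(config=cfg, days=records, repertoires=repertoires)


def _sample_repertoire(
    seqs: list[str],
    masses: np.ndarray,
    depth: int,
    rng: np.random.Generator,
    sample_id: str,
    day: int | None = None,
    subject_id: str = "",
    group: str = "culture",
) -> Repertoire:
    """Multinomial read sample of ``depth`` reads from clone masses."""
    pos = masses > 0
    m = masses[pos]
    kept = [s for s, p in zip(seqs, pos) if p]
    counts = rng.multinomial(depth, m / m.sum())
    clonotypes = [
        Clonotype(cdr3_nt=s, read_count=int(c), chain="IGK")
        for s, c in zip(kept, counts)
        if c > 0
    ]
    return Repertoire(
        sample_id=sample_id,
        clonotypes=clonotypes,
        subject_id=subject_id,
        group=group,
        timepoint=day,
    )


def _heavy_tailed_repertoire(
    rng: np.random.Generator,
    n_clones: int,
    sigma: float,
    size_scale: float,
    sample_id: str,
    subject_id: str = "",
    group: str = "patient",
    timepoint: str | None = None,
    depth: int | None = None,
    length_range: tuple[int, int] = (27, 45),
) -> Repertoire:
    """Repertoire with lognormal(0, sigma) clone sizes scaled by ``size_scale``.

    When ``depth`` is given, reads are multinomially downsampled to that
    total (emulating a sample whose mRNA yield limits sequencing depth).
    """
    n_clones = max(2, int(n_clones))
    sizes = np.maximum(1, np.round(rng.lognormal(0.0, sigma, size=n_clones) * size_scale)).astype(int)
    if depth is not None:
        sizes = rng.multinomial(depth, sizes / sizes.sum())
    seqs = [random_cdr3(rng, length_range) for _ in range(n_clones)]
    clonotypes = [
        Clonotype(cdr3_nt=s, read_count=int(c), chain="IGK")
        for s, c in zip(seqs, sizes)
        if c > 0
    ]
    return Repertoire(
        sample_id=sample_id,
        clonotypes=clonotypes,
        subject_id=subject_id,
        group=group,
        timepoint=timepoint,
    )


def simulate_healthy_cohort(
    n_healthy: int = 12,
    n_clones: int = 5000,
    sigma: float = 1.2,
    size_scale: float = 50.0,
    seed: int = 0,
) -> list[Repertoire]:
    """Healthy-volunteer repertoires: high richness, heavy-tailed clone sizes."""
    rng = np.random.default_rng(seed)
    return [
        _heavy_tailed_repertoire(
            rng,
            n_clones=n_clones,
            sigma=sigma,
            size_scale=size_scale,
            sample_id=f"H{i + 1:02d}",
            subject_id=f"H{i + 1:02d}",
            group="healthy",
        )
        for i in range(n_healthy)
    ]


@dataclass
class PatientCohortConfig:
    """Parameters of the synthetic transplant cohort.

    TP3 recovery is the single knob separating outcomes: the target
    normalized SDI is drawn per patient (non-relapse mean 1.0, relapse mean
    0.6, common sd 0.15) and realized by adjusting the number of novel
    clones, using the generated healthy cohort itself as the calibration
    baseline.  TP2 is sequenced at very low depth (200 reads) because the
    circulating B cell population is nearly ablated there.  Relapse patients
    carry a planted monoclonal tumor clone from TP1 onward, with peripheral
    fraction log-uniform over the clinically observed range [3e-5, 0.014].
    """

    n_relapse: int = 8
    n_nonrelapse: int = 9
    n_healthy: int = 12
    healthy_clones: int = 5000
    sigma: float = 1.2
    size_scale: float = 50.0
    tp1_clones: int = 800
    tp2_clones: int = 40
    tp2_depth: int = 200
    tp3_sdi_mean_nonrelapse: float = 1.0
    tp3_sdi_mean_relapse: float = 0.6
    tp3_sdi_sd: float = 0.15
    tp4_clones: int = 600
    tumor_fraction_range: tuple[float, float] = (3e-5, 0.014)
    seed: int = 0


@dataclass
class SyntheticCohort:
    config: PatientCohortConfig
    records: list[CohortRecord]
    repertoires: dict[tuple[str, str], Repertoire]
    healthy: list[Repertoire]
    signatures: dict[str, TumorSignature]
    planted_clones: dict[str, str] = field(default_factory=dict)
    tumor_repertoires: dict[str, Repertoire] = field(default_factory=dict)


def _plant_clone(rep: Repertoire, seq: str, fraction: float) -> None:
    count = max(1, int(round(fraction * rep.total_reads)))
    rep.clonotypes.append(Clonotype(cdr3_nt=seq, read_count=count, chain="IGK"))


def simulate_patient_cohort(config: PatientCohortConfig | None = None, **overrides) -> SyntheticCohort:
    """Generate the full synthetic cohort: patients, healthy baseline, and
    tumor signatures for relapse patients."""
    cfg = config or PatientCohortConfig()
    if overrides:
        from dataclasses import replace

        cfg = replace(cfg, **overrides)
    rng = np.random.default_rng(cfg.seed)

    healthy = simulate_healthy_cohort(
        n_healthy=cfg.n_healthy,
        n_clones=cfg.healthy_clones,
        sigma=cfg.sigma,
        size_scale=cfg.size_scale,
        seed=int(rng.integers(2**31)),
    )
    # Calibrate the clone-count -> Shannon map on the generated healthy cohort:
    # H ~ ln(n_clones) - c, with c the evenness deficit of the size law.
    h_values = []
    for rep in healthy:
        counts = np.array([c.read_count for c in rep.clonotypes], dtype=float)
        p = counts / counts.sum()
        h_values.append(float(-(p * np.log(p)).sum()))
    h_healthy = float(np.mean(h_values))
    evenness_deficit = float(np.log(cfg.healthy_clones) - h_healthy)

    def clones_for_target(norm_sdi: float) -> int:
        return max(10, int(round(np.exp(norm_sdi * h_healthy + evenness_deficit))))

    n_total = cfg.n_relapse + cfg.n_nonrelapse
    relapse_flags = np.array([True] * cfg.n_relapse + [False] * cfg.n_nonrelapse)
    rng.shuffle(relapse_flags)

    records: list[CohortRecord] = []
    repertoires: dict[tuple[str, str], Repertoire] = {}
    signatures: dict[str, TumorSignature] = {}
    planted: dict[str, str] = {}
    tumor_reps: dict[str, Repertoire] = {}

    lo, hi = cfg.tumor_fraction_range
    for i in range(n_total):
        pid = f"S{i + 1:02d}"
        is_relapse = bool(relapse_flags[i])
        target = rng.normal(
            cfg.tp3_sdi_mean_relapse if is_relapse else cfg.tp3_sdi_mean_nonrelapse,
            cfg.tp3_sdi_sd,
        )
        reps = {
            "TP1": _heavy_tailed_repertoire(
                rng, cfg.tp1_clones, cfg.sigma, cfg.size_scale,
                sample_id=f"{pid}_TP1", subject_id=pid, timepoint="TP1",
            ),
            "TP2": _heavy_tailed_repertoire(
                rng, cfg.tp2_clones, cfg.sigma, cfg.size_scale,
                sample_id=f"{pid}_TP2", subject_id=pid, timepoint="TP2",
                depth=cfg.tp2_depth,
            ),
            "TP3": _heavy_tailed_repertoire(
                rng, clones_for_target(target), cfg.sigma, cfg.size_scale,
                sample_id=f"{pid}_TP3", subject_id=pid, timepoint="TP3",
            ),
        }
        if is_relapse:
            reps["TP4"] = _heavy_tailed_repertoire(
                rng, cfg.tp4_clones, cfg.sigma, cfg.size_scale,
                sample_id=f"{pid}_TP4", subject_id=pid, timepoint="TP4",
            )
            tumor_seq = random_cdr3(rng)
            fraction = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            for rep in reps.values():
                _plant_clone(rep, tumor_seq, fraction)
            planted[pid] = tumor_seq
            # tumor biopsy: dominant clone plus a single-mutation subclone and
            # a minor unrelated clone, as a realistic signature input
            subclone = mutate_sequence(tumor_seq, rng)
            minor = random_cdr3(rng)
            tumor_rep = Repertoire(
                sample_id=f"{pid}_tumor",
                clonotypes=[
                    Clonotype(cdr3_nt=tumor_seq, read_count=9000, chain="IGK"),
                    Clonotype(cdr3_nt=subclone, read_count=800, chain="IGK"),
                    Clonotype(cdr3_nt=minor, read_count=200, chain="IGK"),
                ],
                subject_id=pid,
                group="tumor",
            )
            signatures[pid] = extract_primary_clusters(tumor_rep)
            tumor_reps[pid] = tumor_rep
        for tp, rep in reps.items():
            repertoires[(pid, tp)] = rep

        records.append(
            CohortRecord(
                patient_no=pid,
                age=float(rng.integers(20, 66)),
                sex=str(rng.choice(["M", "F"])),
                subtype=str(rng.choice(["GCB", "non-GCB"])),
                status=str(rng.choice(["Salvage", "Consolidation"])),
                regimen="CBV",
                progression=is_relapse,
                pfs_months=float(np.round(rng.uniform(4, 24) if is_relapse else rng.uniform(17, 47), 1)),
            )
        )

    return SyntheticCohort(
        config=cfg,
        records=records,
        repertoires=repertoires,
        healthy=healthy,
        signatures=signatures,
        planted_clones=planted,
        tumor_repertoires=tumor_reps,
    )
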
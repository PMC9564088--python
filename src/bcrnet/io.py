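"""Reading and writing clonotype tables, cohort metadata, and tumor signatures.

Clonotype tables are tab-delimited files with a header row, in one of three
dialects:

``simple``
    Minimal fixture format: ``cdr3_nt``, ``read_count``, ``chain`` columns
    (``v_gene``, ``j_gene``, ``cdr3_aa`` optional).
``airr``
    AIRR Rearrangement style: ``junction``, ``junction_aa``, ``v_call``,
    ``j_call``, ``duplicate_count``, optional ``locus``.
``mixcr``
    MiXCR clone export style: ``nSeqCDR3``, ``aaSeqCDR3``,
    ``allVHitsWithScore``, ``allJHitsWithScore``, ``cloneCount``.

All downstream analyses treat the CDR3 nucleotide sequence as the clonal
identifier; V/J calls are carried as metadata only.  Rows whose CDR3 contains
any character outside A/C/G/T (after uppercasing) are dropped with a warning,
because network edges are defined on exact nucleotide identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .exceptions import EmptyRepertoireError, RepertoireFormatError

__all__ = [
    "Clonotype",
    "Repertoire",
    "CohortRecord",
    "read_clonotype_table",
    "read_cohort_table",
    "read_tumor_signature",
    "write_repertoire",
    "DIALECTS",
]

VALID_CHAINS = ("IGH", "IGK", "IGL")
_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class Clonotype:
    """One unique CDR3 nucleotide sequence with its observed read count."""

    cdr3_nt: str
    read_count: int
    chain: str = "IGK"
    cdr3_aa: str | None = None
    v_gene: str | None = None
    j_gene: str | None = None

    def __post_init__(self):
        if not self.cdr3_nt or not _ACGT.issuperset(self.cdr3_nt):
            raise ValueError(f"cdr3_nt must be a non-empty A/C/G/T string: {self.cdr3_nt!r}")
        if self.read_count < 1:
            raise ValueError(f"read_count must be >= 1, got {self.read_count}")


@dataclass
class Repertoire:
    """A sample's clonotype collection with subject/timepoint metadata."""

    sample_id: str
    clonotypes: list[Clonotype] = field(default_factory=list)
    subject_id: str = ""
    group: str = "patient"  # healthy | patient | culture | tumor
    timepoint: str | int | None = None

    @property
    def total_reads(self) -> int:
        return sum(c.read_count for c in self.clonotypes)

    def counts_by_sequence(self) -> dict[str, int]:
        """Aggregate read counts by unique CDR3 sequence (network vertex mass)."""
        out: dict[str, int] = {}
        for c in self.clonotypes:
            out[c.cdr3_nt] = out.get(c.cdr3_nt, 0) + c.read_count
        return out

    def __len__(self) -> int:
        return len(self.clonotypes)


@dataclass
class CohortRecord:
    """One patient's demographic/clinical row from the cohort table."""

    patient_no: str
    age: float
    sex: str
    subtype: str
    status: str
    regimen: str
    progression: bool
    pfs_months: float


# dialect -> {canonical field: source column}
DIALECTS: dict[str, dict[str, str]] = {
    "simple": {
        "cdr3_nt": "cdr3_nt",
        "read_count": "read_count",
        "chain": "chain",
        "cdr3_aa": "cdr3_aa",
        "v_gene": "v_gene",
        "j_gene": "j_gene",
    },
    "airr": {
        "cdr3_nt": "junction",
        "cdr3_aa": "junction_aa",
        "v_gene": "v_call",
        "j_gene": "j_call",
        "read_count": "duplicate_count",
        "chain": "locus",
    },
    "mixcr": {
        "cdr3_nt": "nSeqCDR3",
        "cdr3_aa": "aaSeqCDR3",
        "v_gene": "allVHitsWithScore",
        "j_gene": "allJHitsWithScore",
        "read_count": "cloneCount",
    },
}

_REQUIRED = {
    "simple": ("cdr3_nt", "read_count", "chain"),
    "airr": ("cdr3_nt", "read_count"),
    "mixcr": ("cdr3_nt", "read_count"),
}


def _first_hit(call: str | None) -> str | None:
    """'IGKV3-20*00(1250)' or 'IGKV3-20*01,IGKV3-15*01' -> 'IGKV3-20'."""
    if call is None or (isinstance(call, float) and pd.isna(call)) or call == "":
        return None
    hit = str(call).split(",")[0].split("(")[0].strip()
    return hit.split("*")[0] if "*" in hit else hit


def _chain_of(row: dict, dialect: str) -> str | None:
    chain = row.get("chain")
    if chain:
        chain = str(chain).upper()
        return chain if chain in VALID_CHAINS else None
    v = row.get("v_gene")
    if v and str(v)[:3].upper() in VALID_CHAINS:
        return str(v)[:3].upper()
    return None


def read_clonotype_table(
    path: str | Path,
    dialect: str = "simple",
    chain_filter: str | None = "IGK",
) -> Repertoire:
    """Read a clonotype TSV into a validated, merged :class:`Repertoire`.

    Rows failing validation (non-ACGT CDR3, read count < 1, wrong chain when
    ``chain_filter`` is set) are dropped and counted in a single warning.
    Clonotypes identical in (cdr3_nt, v_gene, j_gene) are merged by summing
    read counts.

    Parameters
    ----------
    path
        Tab-delimited file with a header row.
    dialect
        One of ``simple``, ``airr``, ``mixcr``.
    chain_filter
        Keep only this chain (default IGK, the chain used for the clinical
        diversity analyses); ``None`` keeps all chains.
    """
    if dialect not in DIALECTS:
        raise RepertoireFormatError(f"unknown dialect {dialect!r}; expected one of {sorted(DIALECTS)}")
    path = Path(path)
    colmap = DIALECTS[dialect]
    df = pd.read_csv(path, sep="\t", dtype=str)
    for fieldname in _REQUIRED[dialect]:
        col = colmap[fieldname]
        if col not in df.columns:
            raise RepertoireFormatError(
                f"{path.name}: dialect {dialect!r} requires column {col!r} (missing)"
            )

    merged: dict[tuple, dict] = {}
    n_dropped = 0
    for _, raw in df.iterrows():
        row = {f: raw.get(col) for f, col in colmap.items() if col in df.columns}
        seq = row.get("cdr3_nt")
        if seq is None or pd.isna(seq):
            n_dropped += 1
            continue
        seq = str(seq).upper()
        try:
            count = int(round(float(row["read_count"])))
        except (TypeError, ValueError):
            n_dropped += 1
            continue
        if not seq or not _ACGT.issuperset(seq) or count < 1:
            n_dropped += 1
            continue
        if dialect == "mixcr":
            row["v_gene"] = _first_hit(row.get("v_gene"))
            row["j_gene"] = _first_hit(row.get("j_gene"))
        chain = _chain_of(row, dialect)
        if chain_filter is not None:
            if chain != chain_filter:
                n_dropped += 1
                continue
        key = (seq, row.get("v_gene") or None, row.get("j_gene") or None)
        if key in merged:
            merged[key]["read_count"] += count
        else:
            aa = row.get("cdr3_aa")
            merged[key] = {
                "cdr3_nt": seq,
                "read_count": count,
                "chain": chain or (chain_filter or "IGK"),
                "cdr3_aa": None if aa is None or pd.isna(aa) else str(aa),
                "v_gene": key[1],
                "j_gene": key[2],
            }

    if n_dropped:
        warnings.warn(f"{path.name}: dropped {n_dropped} invalid/filtered rows", stacklevel=2)
    if not merged:
        raise EmptyRepertoireError(f"{path.name}: no valid clonotypes after validation")
    clonotypes = [Clonotype(**kw) for kw in merged.values()]
    return Repertoire(sample_id=path.stem, clonotypes=clonotypes)


def write_repertoire(repertoire: Repertoire, path: str | Path) -> None:
    """Write a repertoire in the ``simple`` TSV dialect (round-trip safe)."""
    rows = [
        {
            "cdr3_nt": c.cdr3_nt,
            "read_count": c.read_count,
            "chain": c.chain,
            "cdr3_aa": c.cdr3_aa or "",
            "v_gene": c.v_gene or "",
            "j_gene": c.j_gene or "",
        }
        for c in repertoire.clonotypes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_COHORT_COLS = {
    "patient_no": ("no.", "no", "patient_no", "patient"),
    "age": ("age",),
    "sex": ("sex",),
    "subtype": ("subtypes", "subtype"),
    "status": ("status",),
    "regimen": ("conditioning regimen", "regimen"),
    "progression": ("progression",),
    "pfs_months": ("pfs", "pfs_months"),
}


def read_cohort_table(path: str | Path) -> list[CohortRecord]:
    """Read the patient cohort table (demographics, treatment, outcome).

    Accepts the published column layout (No., Age, Sex, Subtypes, Status,
    Conditioning Regimen, Progression, PFS) or snake_case equivalents.
    Progression is parsed from Yes/No.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    lower = {c.lower().strip(): c for c in df.columns}
    resolved: dict[str, str] = {}
    for fieldname, aliases in _COHORT_COLS.items():
        for a in aliases:
            if a in lower:
                resolved[fieldname] = lower[a]
                break
        else:
            raise RepertoireFormatError(
                f"{path.name}: cohort table missing column for {fieldname!r} "
                f"(accepted: {aliases})"
            )
    records = []
    for _, raw in df.iterrows():
        pid = str(raw[resolved["patient_no"]]).strip()
        prog_raw = str(raw[resolved["progression"]]).strip().lower()
        if prog_raw in ("yes", "true", "1"):
            progression = True
        elif prog_raw in ("no", "false", "0"):
            progression = False
        else:
            raise RepertoireFormatError(
                f"{path.name}: patient {pid}: unparseable progression value {prog_raw!r}"
            )
        try:
            pfs = float(raw[resolved["pfs_months"]])
        except (TypeError, ValueError) as exc:
            raise RepertoireFormatError(f"{path.name}: patient {pid}: unparseable PFS") from exc
        records.append(
            CohortRecord(
                patient_no=pid,
                age=float(raw[resolved["age"]]),
                sex=str(raw[resolved["sex"]]).strip(),
                subtype=str(raw[resolved["subtype"]]).strip(),
                status=str(raw[resolved["status"]]).strip(),
                regimen=str(raw[resolved["regimen"]]).strip(),
                progression=progression,
                pfs_months=pfs,
            )
        )
    return records


#: pseudo-count scale used when a tumor signature lists clone fractions
#: instead of read counts; preserves printed ratios to <= 1e-6 relative error.
FRACTION_SCALE = 1_000_000


def read_tumor_signature(path: str | Path, fraction_tolerance: float = 1e-3) -> Repertoire:
    """Read a tumor CDR3 signature table into a tumor :class:`Repertoire`.

    Rows carry ``cdr3_nt`` plus either ``read_count`` or ``fraction`` (the
    clone's share of the tumor BCR population; '86.2%' or 0.862 both accepted).
    Fractions are converted to pseudo-counts preserving their ratios.  An
    optional ``patient_no`` column is ignored here; use
    :func:`tumor_signature_from_frame` to handle multi-patient files.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    return tumor_signature_from_frame(df, name=path.stem, fraction_tolerance=fraction_tolerance)


def tumor_signature_from_frame(
    df: pd.DataFrame, name: str = "tumor", fraction_tolerance: float = 1e-3
) -> Repertoire:
    """Build a tumor repertoire from an in-memory signature table."""
    if "cdr3_nt" not in df.columns:
        raise RepertoireFormatError(f"{name}: tumor signature requires column 'cdr3_nt'")
    has_count = "read_count" in df.columns
    has_frac = "fraction" in df.columns or "ratio" in df.columns
    if not (has_count or has_frac):
        raise RepertoireFormatError(
            f"{name}: tumor signature requires 'read_count' or 'fraction'/'ratio'"
        )
    frac_col = "fraction" if "fraction" in df.columns else ("ratio" if "ratio" in df.columns else None)

    clonotypes: list[Clonotype] = []
    n_dropped = 0
    fractions: list[float] = []
    seqs: list[str] = []
    for _, raw in df.iterrows():
        seq = str(raw["cdr3_nt"]).upper() if not pd.isna(raw["cdr3_nt"]) else ""
        if not seq or not _ACGT.issuperset(seq):
            n_dropped += 1
            continue
        if has_count and not pd.isna(raw.get("read_count")):
            count = int(round(float(raw["read_count"])))
            if count < 1:
                n_dropped += 1
                continue
            clonotypes.append(Clonotype(cdr3_nt=seq, read_count=count))
        else:
            val = str(raw[frac_col]).strip()
            frac = float(val.rstrip("%")) / 100.0 if val.endswith("%") else float(val)
            if frac <= 0:
                n_dropped += 1
                continue
            fractions.append(frac)
            seqs.append(seq)
    if fractions:
        if sum(fractions) > 1.0 + fraction_tolerance:
            raise RepertoireFormatError(
                f"{name}: clone fractions sum to {sum(fractions):.4f} > 1"
            )
        for seq, frac in zip(seqs, fractions):
            clonotypes.append(Clonotype(cdr3_nt=seq, read_count=int(round(frac * FRACTION_SCALE))))
    if n_dropped:
        warnings.warn(f"{name}: dropped {n_dropped} invalid tumor signature rows", stacklevel=2)
    if not clonotypes:
        raise EmptyRepertoireError(f"{name}: no valid tumor clones")
    return Repertoire(sample_id=name, clonotypes=clonotypes, group="tumor")


def with_metadata(rep: Repertoire, **kw) -> Repertoire:
    """Return a shallow copy of ``rep`` with metadata fields replaced."""
    return replace(rep, **kw)
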
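"""Tumor-clone tracking in peripheral repertoires (minimal residual disease).

The primary tumor BCR cluster is the set of network clusters that each hold
at least 5% of the tumor's BCR reads.  Its member sequences are searched
against a patient's peripheral repertoire at each timepoint by Levenshtein
(edit) distance:

* closest LD = 0  -> the tumor clone pre-exists in blood: MRD positive;
* closest LD = 1  -> a single-mutation relative is present: reported as
  *related* evidence of ongoing clonal evolution, but MRD stays negative;
* larger LD       -> the tumor clone is absent.

``tumor_fraction`` is the share of peripheral reads carried by exact matches
to primary tumor sequences.  ``spike_in_network`` overlays the tumor cluster
onto the peripheral network for visualization, coloring tumor vertices by
whether they pre-existed in blood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from .exceptions import EmptyRepertoireError
from .io import Clonotype, Repertoire
from .network import ClonalNetwork, build_network, cluster_abundances

__all__ = [
    "levenshtein",
    "TumorSignature",
    "extract_primary_clusters",
    "MRDMatch",
    "MRDReport",
    "match_tumor_clones",
    "tumor_fraction",
    "spike_in_network",
]

PRIMARY_THRESHOLD = 0.05
RELATED_MAX = 1


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (substitution, insertion, deletion).

    Delegates to edlib's banded bit-vector algorithm, which returns exact
    distances without a band limit when ``k`` is unset.
    """
    if a == b:
        return 0
    if not a or not b:
        return abs(len(a) - len(b))
    return int(edlib.align(a, b, task="distance")["editDistance"])


@dataclass
class TumorSignature:
    """Tumor repertoire clusters with their read fractions and primary flags.

    ``clusters[k]`` is the sorted list of member CDR3 sequences of tumor
    network cluster k; ``fractions[k]`` its collective share of tumor reads;
    ``primary[k]`` whether that share reaches ``threshold``.
    """

    patient_id: str
    clusters: list[list[str]] = field(default_factory=list)
    fractions: list[float] = field(default_factory=list)
    primary: list[bool] = field(default_factory=list)
    threshold: float = PRIMARY_THRESHOLD

    @property
    def primary_sequences(self) -> list[str]:
        """All member sequences of primary clusters, sorted and unique."""
        seqs: set[str] = set()
        for members, is_primary in zip(self.clusters, self.primary):
            if is_primary:
                seqs.update(members)
        return sorted(seqs)

    @property
    def n_primary(self) -> int:
        return sum(self.primary)


def extract_primary_clusters(
    tumor: Repertoire,
    threshold: float = PRIMARY_THRESHOLD,
    neighbor_rule: str = "hamming1",
) -> TumorSignature:
    """Cluster a tumor repertoire and flag clusters holding >= ``threshold``
    of total tumor reads as primary.  All clusters are retained with flags."""
    if not tumor.clonotypes:
        raise EmptyRepertoireError("tumor repertoire is empty")
    net = build_network(tumor, neighbor_rule=neighbor_rule)
    abundances = cluster_abundances(net)
    total = sum(abundances)
    members: list[list[str]] = [[] for _ in range(net.n_clusters)]
    for i, cid in enumerate(net.cluster_of):
        members[cid].append(net.sequences[i])
    fractions = [a / total for a in abundances]
    return TumorSignature(
        patient_id=tumor.subject_id or tumor.sample_id,
        clusters=[sorted(m) for m in members],
        fractions=fractions,
        primary=[f >= threshold for f in fractions],
        threshold=threshold,
    )


@dataclass
class MRDMatch:
    """Closest peripheral match for one primary tumor sequence."""

    tumor_sequence: str
    closest_sequence: str | None
    distance: int | None  # None when the peripheral repertoire is empty
    mrd_positive: bool
    related: bool


@dataclass
class MRDReport:
    """Per-timepoint MRD evidence for a patient's tumor signature."""

    patient_id: str
    timepoint: str | int | None
    matches: list[MRDMatch]
    tumor_fraction: float

    @property
    def mrd_positive(self) -> bool:
        return any(m.mrd_positive for m in self.matches)

    @property
    def min_distance(self) -> int | None:
        ds = [m.distance for m in self.matches if m.distance is not None]
        return min(ds) if ds else None


def match_tumor_clones(
    signature: TumorSignature,
    peripheral: Repertoire,
    related_max: int = RELATED_MAX,
) -> MRDReport:
    """Closest-LD search of primary tumor sequences against a peripheral
    repertoire.

    Ties on distance are broken by the lexicographically smallest peripheral
    sequence.  MRD positivity requires an exact match (LD = 0); distances in
    ``1..related_max`` set the ``related`` flag only.
    """
    peripheral_seqs = sorted(peripheral.counts_by_sequence())
    matches: list[MRDMatch] = []
    for tseq in signature.primary_sequences:
        best_seq: str | None = None
        best_d: int | None = None
        for pseq in peripheral_seqs:  # lexicographic order makes ties deterministic
            d = levenshtein(tseq, pseq)
            if best_d is None or d < best_d:
                best_seq, best_d = pseq, d
                if d == 0:
                    break
        matches.append(
            MRDMatch(
                tumor_sequence=tseq,
                closest_sequence=best_seq,
                distance=best_d,
                mrd_positive=best_d == 0,
                related=best_d is not None and 1 <= best_d <= related_max,
            )
        )
    return MRDReport(
        patient_id=signature.patient_id,
        timepoint=peripheral.timepoint,
        matches=matches,
        tumor_fraction=tumor_fraction(signature, peripheral),
    )


def tumor_fraction(signature: TumorSignature, peripheral: Repertoire) -> float:
    """Share of peripheral reads whose CDR3 exactly equals a primary tumor
    sequence.  Related (LD >= 1) clones do not count."""
    counts = peripheral.counts_by_sequence()
    total = sum(counts.values())
    if total == 0:
        return 0.0
    tumor_reads = sum(counts.get(s, 0) for s in signature.primary_sequences)
    return tumor_reads / total


def spike_in_network(
    signature: TumorSignature,
    peripheral: Repertoire,
    neighbor_rule: str = "hamming1",
) -> ClonalNetwork:
    """Network over the union of peripheral and primary tumor sequences.

    Tumor vertices are labeled ``tumor_mrd`` when the sequence pre-exists in
    blood (keeping its peripheral read count) or ``tumor_absent`` otherwise
    (spiked in with nominal count 1); peripheral-only vertices keep the
    ``normal`` label.  Edges follow the standard neighbor rule, so related
    peripheral clones connect to the tumor vertex.
    """
    counts = peripheral.counts_by_sequence()
    tumor_seqs = set(signature.primary_sequences)
    spiked = list(peripheral.clonotypes)
    chain = peripheral.clonotypes[0].chain if peripheral.clonotypes else "IGK"
    for seq in sorted(tumor_seqs - set(counts)):
        spiked.append(Clonotype(cdr3_nt=seq, read_count=1, chain=chain))
    union = Repertoire(
        sample_id=f"{peripheral.sample_id}+tumor",
        clonotypes=spiked,
        subject_id=peripheral.subject_id,
        group=peripheral.group,
        timepoint=peripheral.timepoint,
    )
    net = build_network(union, neighbor_rule=neighbor_rule)
    for i, seq in enumerate(net.sequences):
        if seq in tumor_seqs:
            net.labels[i] = "tumor_mrd" if seq in counts else "tumor_absent"
    return net
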
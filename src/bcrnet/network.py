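"""Repertoire similarity networks.

Each vertex is a unique CDR3 nucleotide sequence; its mass is the number of
identical reads aggregated across clonotypes.  Edges join vertices that differ
by a single nucleotide.  A clone (cluster) is a connected component: a group
of clonally related B cells whose CDR3s are identical or linked by chains of
single point mutations.

Two neighbor rules are supported:

``hamming1`` (default)
    Equal length and Hamming distance exactly 1 — single point mutations
    (substitutions) only.
``levenshtein1``
    Levenshtein distance exactly 1, i.e. hamming1 pairs plus single-indel
    pairs (length difference 1 where the shorter sequence is a deletion of
    the longer).

Neighbor search uses position-masked key hashing (expected near-linear in the
number of sequences) instead of all-pairs distance computation; the two are
equivalent and the brute-force version is retained as a test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .exceptions import ValidationError
from .io import Repertoire

__all__ = [
    "ClonalNetwork",
    "build_network",
    "neighbor_pairs",
    "cluster_abundances",
    "layout_fr",
    "write_graphml",
    "write_edge_list",
]

NEIGHBOR_RULES = ("hamming1", "levenshtein1")
MAX_SEQUENCE_LENGTH = 1000


@dataclass
class ClonalNetwork:
    """Vertices (unique sequences with masses), single-mutation edges, and
    connected-component clusters.

    ``sequences[i]`` is vertex i's CDR3; ``counts[i]`` its aggregated read
    count; ``labels[i]`` an optional annotation (``normal``, ``tumor_mrd``,
    ``tumor_absent``, ``novel``, ``naive``).  ``cluster_of[i]`` maps vertex i
    to its cluster id; cluster ids run 0..k-1 in decreasing aggregate-count
    order, ties broken by the lexicographically smallest member sequence.
    """

    sequences: list[str] = field(default_factory=list)
    counts: list[int] = field(default_factory=list)
    edges: list[tuple[int, int]] = field(default_factory=list)
    cluster_of: list[int] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)
    neighbor_rule: str = "hamming1"

    @property
    def n_vertices(self) -> int:
        return len(self.sequences)

    @property
    def n_clusters(self) -> int:
        return max(self.cluster_of) + 1 if self.cluster_of else 0

    def index_of(self, seq: str) -> int | None:
        if not hasattr(self, "_index"):
            self._index = {s: i for i, s in enumerate(self.sequences)}
        return self._index.get(seq)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, seq in enumerate(self.sequences):
            g.add_node(
                i,
                sequence=seq,
                count=self.counts[i],
                cluster_id=self.cluster_of[i],
                label=self.labels[i],
            )
        g.add_edges_from(self.edges)
        return g


def _hamming1_pairs(sequences: list[str]) -> list[tuple[int, int]]:
    """Pairs at Hamming distance exactly 1 via position-masked key hashing.

    For every sequence and every position, the key is the sequence with that
    position wildcarded.  Two unique sequences share a key iff they have equal
    length and differ exactly at the masked position, so every masked-key
    bucket is a clique of neighbors and every neighbor pair lands in exactly
    one bucket.  Sequences are grouped by length and encoded as a byte
    matrix; bucketing one masked position is then a vectorized row sort.
    """
    import numpy as np

    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(sequences):
        by_len.setdefault(len(s), []).append(i)

    pairs: list[tuple[int, int]] = []
    for length, idx in by_len.items():
        if len(idx) < 2 or length == 0:
            continue
        arr = np.frombuffer("".join(sequences[i] for i in idx).encode(), dtype=np.uint8)
        arr = arr.reshape(len(idx), length)
        idx_arr = np.asarray(idx)
        for p in range(length):
            masked = arr.copy()
            masked[:, p] = 0
            keys = np.ascontiguousarray(masked).view(np.dtype((np.void, length))).ravel()
            order = np.argsort(keys, kind="stable")
            sorted_keys = keys[order]
            same = sorted_keys[1:] == sorted_keys[:-1]
            if not same.any():
                continue
            # runs of equal masked keys are neighbor cliques; visit only
            # the runs that actually contain duplicates
            starts = np.concatenate(([0], np.flatnonzero(~same) + 1, [len(keys)]))
            widths = np.diff(starts)
            for r in np.flatnonzero(widths > 1):
                members = idx_arr[order[starts[r] : starts[r] + widths[r]]]
                for a in range(len(members)):
                    for b_ in range(a + 1, len(members)):
                        i, j = int(members[a]), int(members[b_])
                        pairs.append((i, j) if i < j else (j, i))
    return pairs


def _indel1_pairs(sequences: list[str]) -> list[tuple[int, int]]:
    """Pairs where the shorter sequence equals the longer with one base deleted."""
    by_seq: dict[str, int] = {s: i for i, s in enumerate(sequences)}
    pairs: set[tuple[int, int]] = set()
    for i, s in enumerate(sequences):
        for p in range(len(s)):
            short = s[:p] + s[p + 1 :]
            j = by_seq.get(short)
            if j is not None and j != i:
                pairs.add((i, j) if i < j else (j, i))
    return sorted(pairs)


def neighbor_pairs(sequences: list[str], neighbor_rule: str = "hamming1") -> list[tuple[int, int]]:
    """Index pairs of single-mutation neighbors among unique sequences.

    Output is sorted and identical to brute-force all-pairs distance checks.
    Raises :class:`ValidationError` if sequences are not unique.
    """
    if len(set(sequences)) != len(sequences):
        raise ValidationError("neighbor_pairs requires unique sequences")
    if neighbor_rule not in NEIGHBOR_RULES:
        raise ValidationError(f"unknown neighbor rule {neighbor_rule!r}")
    pairs = _hamming1_pairs(sequences)
    if neighbor_rule == "levenshtein1":
        pairs = sorted(set(pairs) | set(_indel1_pairs(sequences)))
    else:
        pairs = sorted(pairs)
    return pairs


def build_network(repertoire: Repertoire, neighbor_rule: str = "hamming1") -> ClonalNetwork:
    """Build the clonal network of a repertoire.

    Vertices are unique CDR3 sequences with read counts summed across
    clonotypes (V/J calls do not split vertices); edges follow
    ``neighbor_rule``; clusters are connected components with deterministic
    ids (aggregate count descending, then smallest member sequence).
    An empty repertoire yields an empty network.
    """
    mass = repertoire.counts_by_sequence()
    for s in mass:
        if len(s) > MAX_SEQUENCE_LENGTH:
            raise ValidationError(f"sequence longer than {MAX_SEQUENCE_LENGTH} nt: {len(s)} nt")
    sequences = sorted(mass)  # deterministic vertex order
    counts = [mass[s] for s in sequences]
    if not sequences:
        return ClonalNetwork(neighbor_rule=neighbor_rule)
    edges = neighbor_pairs(sequences, neighbor_rule)

    g = nx.Graph()
    g.add_nodes_from(range(len(sequences)))
    g.add_edges_from(edges)
    components = [sorted(c) for c in nx.connected_components(g)]
    # cluster id: decreasing aggregate count, ties by smallest member sequence
    components.sort(key=lambda c: (-sum(counts[i] for i in c), sequences[c[0]]))
    cluster_of = [0] * len(sequences)
    for cid, comp in enumerate(components):
        for i in comp:
            cluster_of[i] = cid
    return ClonalNetwork(
        sequences=sequences,
        counts=counts,
        edges=edges,
        cluster_of=cluster_of,
        labels=["normal"] * len(sequences),
        neighbor_rule=neighbor_rule,
    )


def cluster_abundances(network: ClonalNetwork) -> list[int]:
    """Aggregate read count per cluster, ordered by cluster id."""
    sums = [0] * network.n_clusters
    for i, cid in enumerate(network.cluster_of):
        sums[cid] += network.counts[i]
    return sums


def layout_fr(network: ClonalNetwork, iterations: int = 50, seed: int = 0) -> dict[int, tuple[float, float]]:
    """Fruchterman–Reingold force-directed layout (deterministic per seed)."""
    if iterations < 1:
        raise ValidationError("iterations must be >= 1")
    if network.n_vertices == 0:
        return {}
    pos = nx.spring_layout(network.to_networkx(), iterations=iterations, seed=seed)
    return {i: (float(xy[0]), float(xy[1])) for i, xy in pos.items()}


def write_graphml(network: ClonalNetwork, path: str | Path,
                  layout: dict[int, tuple[float, float]] | None = None) -> None:
    """Export with per-vertex sequence, count, cluster_id, label (and x/y)."""
    g = network.to_networkx()
    if layout:
        for i, (x, y) in layout.items():
            g.nodes[i]["x"] = x
            g.nodes[i]["y"] = y
    nx.write_graphml(g, str(path))


def write_edge_list(network: ClonalNetwork, vertex_path: str | Path, edge_path: str | Path) -> None:
    """Plain-text alternative to GraphML: a vertex table and an edge table."""
    pd.DataFrame(
        {
            "vertex_id": range(network.n_vertices),
            "sequence": network.sequences,
            "count": network.counts,
            "cluster_id": network.cluster_of,
            "label": network.labels,
        }
    ).to_csv(vertex_path, sep="\t", index=False)
    pd.DataFrame(network.edges, columns=["source", "target"]).to_csv(edge_path, sep="\t", index=False)
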
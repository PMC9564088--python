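"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from bcrnet.io import Clonotype, Repertoire


def dp_levenshtein(a: str, b: str) -> int:
    """Quadratic dynamic-programming edit distance (independent oracle)."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def brute_force_pairs(sequences: list[str], rule: str) -> list[tuple[int, int]]:
    """All-pairs neighbor search (independent oracle for both edge rules)."""
    out = []
    for i in range(len(sequences)):
        for j in range(i + 1, len(sequences)):
            a, b = sequences[i], sequences[j]
            if rule == "hamming1":
                hit = len(a) == len(b) and sum(x != y for x, y in zip(a, b)) == 1
            else:
                # LD >= |len(a) - len(b)|, so only near-equal lengths need DP
                hit = abs(len(a) - len(b)) <= 1 and dp_levenshtein(a, b) == 1
            if hit:
                out.append((i, j))
    return out


def rank_statistic_auc(scores, labels, positive="non_relapse") -> float:
    """AUC as P(score_pos > score_neg) + 0.5 P(equal) over all cross-pairs."""
    pos = [s for s, lab in zip(scores, labels) if lab == positive]
    neg = [s for s, lab in zip(scores, labels) if lab != positive]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def make_repertoire(counts: dict[str, int], sample_id="test", **kw) -> Repertoire:
    clonotypes = [Clonotype(cdr3_nt=s, read_count=c) for s, c in counts.items()]
    return Repertoire(sample_id=sample_id, clonotypes=clonotypes, **kw)


def random_sequences(rng: np.random.Generator, n: int, lengths=(8, 12), cluster_bias=0.5):
    """Unique random sequences; with probability ``cluster_bias`` a sequence
    is a 1-mutation variant of an earlier one, so edges actually occur."""
    from bcrnet.simulate import mutate_sequence

    seqs: list[str] = []
    seen = set()
    while len(seqs) < n:
        if seqs and rng.random() < cluster_bias:
            s = mutate_sequence(seqs[int(rng.integers(len(seqs)))], rng)
        else:
            length = int(rng.integers(lengths[0], lengths[1] + 1))
            s = "".join(rng.choice(list("ACGT"), size=length))
        if s not in seen:
            seen.add(s)
            seqs.append(s)
    return seqs


@pytest.fixture
def toy_repertoire() -> Repertoire:
    """Three clones, one Hamming-1 pair: 2 clusters of mass 7 each."""
    return make_repertoire({"AAA": 5, "AAT": 2, "GGG": 7})


@pytest.fixture
def simple_tsv(tmp_path):
    """Write a clonotype table in the simple dialect and return its path."""

    def write(rows, name="sample.tsv", header=("cdr3_nt", "read_count", "chain")):
        path = tmp_path / name
        lines = ["\t".join(header)]
        lines += ["\t".join(str(x) for x in row) for row in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return write
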
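"""Synthetic-data generators: point mutation, co-culture dynamics, cohorts."""

import numpy as np
import pytest

from bcrnet.diversity import shannon
from bcrnet.network import build_network
from bcrnet.simulate import (
    mutate_sequence,
    simulate_coculture,
    simulate_healthy_cohort,
    simulate_patient_cohort,
)
from bcrnet.tracking import match_tumor_clones


def hamming(a, b):
    return sum(x != y for x, y in zip(a, b)) if len(a) == len(b) else None


class TestMutateSequence:
    def test_always_hamming_distance_one(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGT"), size=rng.integers(5, 40)))
            mut = mutate_sequence(seq, rng)
            assert len(mut) == len(seq)
            assert hamming(seq, mut) == 1

    def test_all_variants_reachable(self):
        # 12000 draws on a 3-mer: all 9 single-substitution variants occur
        rng = np.random.default_rng(1)
        seen = {mutate_sequence("ACG", rng) for _ in range(12000)}
        assert len(seen) == 9


class TestCoculture:
    def test_cumulative_fold_reaches_2000_by_day_14(self):
        res = simulate_coculture(tumor_seed=0, mode="mean_field", seed=0)
        assert res.day_record(14).cumulative_fold >= 2000

    def test_day0_tumor_fraction_exact(self):
        res = simulate_coculture(tumor_seed=1, mode="mean_field", seed=0)
        assert res.days[0].tumor_fraction == pytest.approx(1 / 100_001)
        res10 = simulate_coculture(tumor_seed=10, mode="mean_field", seed=0)
        assert res10.days[0].tumor_fraction == pytest.approx(10 / 100_010)

    def test_mean_field_sdi_nondecreasing_through_day12_no_tumor(self):
        res = simulate_coculture(tumor_seed=0, mode="mean_field", seed=2)
        sdis = [r.sdi for r in res.days if r.day <= 12]
        assert all(b >= a - 1e-9 for a, b in zip(sdis, sdis[1:]))
        assert res.day_of_max_sdi() >= 12

    def test_tumor_delays_peak_diversity_mean_field(self):
        no_tumor = simulate_coculture(tumor_seed=0, mode="mean_field", seed=3)
        with_tumor = simulate_coculture(tumor_seed=100, mode="mean_field", seed=3)
        assert no_tumor.day_of_max_sdi() <= 12
        assert with_tumor.day_of_max_sdi() >= 14

    def test_tumor_suppresses_day12_diversity_stochastic(self):
        # the configured suppression makes the effect visible at every seed
        for seed in range(1, 4):
            r0 = simulate_coculture(tumor_seed=0, mode="stochastic", seed=seed)
            r100 = simulate_coculture(tumor_seed=100, mode="stochastic", seed=seed)
            assert r100.day_record(12).sdi < r0.day_record(12).sdi

    def test_replating_caps_population(self):
        res = simulate_coculture(tumor_seed=0, mode="mean_field", seed=0)
        for rec in res.days:
            if rec.day in (8, 12, 16):
                assert rec.n_normal + rec.n_tumor <= 1e5 + 1

    def test_shm_daughters_are_network_neighbors(self):
        res = simulate_coculture(tumor_seed=0, mode="mean_field", seed=4, sample_depth=5000)
        net = build_network(res.repertoires[12])
        # diversified culture: the sampled repertoire contains Hamming-1 lineages
        assert len(net.edges) > 0
        assert net.n_clusters < net.n_vertices

    def test_bit_reproducible(self):
        a = simulate_coculture(tumor_seed=10, mode="stochastic", seed=9)
        b = simulate_coculture(tumor_seed=10, mode="stochastic", seed=9)
        assert a.sdi_by_day() == b.sdi_by_day()
        assert [c.cdr3_nt for c in a.repertoires[14].clonotypes] == [
            c.cdr3_nt for c in b.repertoires[14].clonotypes
        ]


class TestHealthyCohort:
    def test_default_count_and_determinism(self):
        cohort = simulate_healthy_cohort(seed=0)
        assert len(cohort) == 12
        again = simulate_healthy_cohort(seed=0)
        assert [r.counts_by_sequence() for r in cohort] == [
            r.counts_by_sequence() for r in again
        ]

    def test_healthy_sdi_exceeds_ablated_patient_sdi(self):
        # TP2 samples are near-ablated: far fewer clones at tiny depth
        for seed in range(3):
            healthy = simulate_healthy_cohort(n_healthy=3, n_clones=2000, seed=seed)
            cohort = simulate_patient_cohort(
                seed=seed, n_relapse=2, n_nonrelapse=2, n_healthy=2, healthy_clones=2000
            )
            h_min = min(
                shannon(list(r.counts_by_sequence().values())) for r in healthy
            )
            tp2_max = max(
                shannon(list(rep.counts_by_sequence().values()))
                for (pid, tp), rep in cohort.repertoires.items()
                if tp == "TP2"
            )
            assert h_min > tp2_max


@pytest.fixture(scope="module")
def cohort():
    return simulate_patient_cohort(seed=3)


class TestPatientCohort:
    def test_default_composition(self, cohort):
        assert len(cohort.records) == 17
        assert sum(r.progression for r in cohort.records) == 8
        assert len(cohort.healthy) == 12
        assert set(cohort.signatures) == {
            r.patient_no for r in cohort.records if r.progression
        }

    def test_relapse_patients_have_tp4_nonrelapse_do_not(self, cohort):
        for rec in cohort.records:
            assert ((rec.patient_no, "TP4") in cohort.repertoires) == rec.progression

    def test_planted_clone_recovered_at_every_timepoint(self, cohort):
        for pid, sig in cohort.signatures.items():
            for tp in ("TP1", "TP2", "TP3", "TP4"):
                report = match_tumor_clones(sig, cohort.repertoires[(pid, tp)])
                assert report.mrd_positive, (pid, tp)
                assert report.tumor_fraction > 0

    def test_nonrelapse_patients_are_mrd_negative(self, cohort):
        nonrelapse = [r.patient_no for r in cohort.records if not r.progression]
        some_sig = next(iter(cohort.signatures.values()))
        for pid in nonrelapse:
            for tp in ("TP1", "TP2", "TP3"):
                report = match_tumor_clones(some_sig, cohort.repertoires[(pid, tp)])
                assert not report.mrd_positive

    def test_tp3_group_separation_in_configured_direction(self):
        # effect size 0.4 vs sd 0.15: group means must separate in most seeds
        wins = 0
        for seed in range(6):
            c = simulate_patient_cohort(
                seed=seed, n_relapse=4, n_nonrelapse=4, n_healthy=4, healthy_clones=1500
            )
            h_mean = np.mean(
                [shannon(list(r.counts_by_sequence().values())) for r in c.healthy]
            )
            rel, non = [], []
            for rec in c.records:
                rep = c.repertoires[(rec.patient_no, "TP3")]
                sdi = shannon(list(rep.counts_by_sequence().values())) / h_mean
                (rel if rec.progression else non).append(sdi)
            wins += np.mean(non) > np.mean(rel)
        assert wins >= 5

    def test_reproducible_given_seed(self):
        a = simulate_patient_cohort(seed=7, n_relapse=2, n_nonrelapse=2, n_healthy=2,
                                    healthy_clones=500)
        b = simulate_patient_cohort(seed=7, n_relapse=2, n_nonrelapse=2, n_healthy=2,
                                    healthy_clones=500)
        assert a.planted_clones == b.planted_clones
        assert [r.patient_no for r in a.records] == [r.patient_no for r in b.records]
        for key in a.repertoires:
            assert a.repertoires[key].counts_by_sequence() == b.repertoires[key].counts_by_sequence()
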
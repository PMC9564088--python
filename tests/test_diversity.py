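"""Diversity indices, normalization, trajectories, and V-gene usage."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcrnet.diversity import (
    delta_sdi,
    diversity_profile,
    gini,
    gini_simpson,
    normalize_to_healthy,
    rarefy,
    shannon,
    v_gene_usage,
)
from bcrnet.exceptions import DegenerateDataError, EmptyRepertoireError, ValidationError
from bcrnet.io import Clonotype, Repertoire
from bcrnet.network import build_network

from .conftest import make_repertoire

counts_strategy = st.lists(st.integers(min_value=1, max_value=10_000), min_size=1, max_size=50)


class TestIndices:
    def test_shannon_uniform_is_log_n(self):
        assert shannon([1, 1, 1, 1]) == pytest.approx(math.log(4))

    def test_shannon_single_clone_is_zero(self):
        assert shannon([7]) == 0.0

    def test_shannon_direct_evaluation(self):
        # -(0.5 ln 0.5 + 2 * 0.25 ln 0.25)
        assert shannon([50, 25, 25]) == pytest.approx(1.0397, abs=1e-4)

    def test_shannon_log_base_option(self):
        assert shannon([1, 1, 1, 1], base=2) == pytest.approx(2.0)

    def test_gini_simpson_uniform(self):
        assert gini_simpson([5, 5]) == pytest.approx(0.5)
        assert gini_simpson([9]) == 0.0

    def test_gini_simpson_direct(self):
        assert gini_simpson([1, 3]) == pytest.approx(0.375)

    def test_gini_equal_counts_zero(self):
        assert gini([4, 4, 4]) == pytest.approx(0.0)

    def test_gini_pairwise_formula(self):
        assert gini([1, 3]) == pytest.approx(0.25)
        assert gini([1, 1, 1, 97]) == pytest.approx(0.72)

    @pytest.mark.parametrize("fn", [shannon, gini_simpson, gini])
    def test_empty_or_nonpositive_rejected(self, fn):
        with pytest.raises(EmptyRepertoireError):
            fn([])
        with pytest.raises(ValidationError):
            fn([3, 0, 2])

    @given(counts=counts_strategy, factor=st.integers(min_value=2, max_value=50))
    @settings(max_examples=60, deadline=None)
    def test_scale_invariance(self, counts, factor):
        scaled = [c * factor for c in counts]
        assert shannon(scaled) == pytest.approx(shannon(counts), abs=1e-9)
        assert gini_simpson(scaled) == pytest.approx(gini_simpson(counts), abs=1e-9)
        assert gini(scaled) == pytest.approx(gini(counts), abs=1e-9)

    @given(counts=counts_strategy)
    @settings(max_examples=60, deadline=None)
    def test_index_bounds(self, counts):
        n = len(counts)
        h = shannon(counts)
        assert 0.0 <= h <= math.log(n) + 1e-9
        assert 0.0 <= gini_simpson(counts) < 1.0
        assert 0.0 <= gini(counts) < 1.0

    @given(counts=counts_strategy)
    @settings(max_examples=30, deadline=None)
    def test_gini_matches_pairwise_definition(self, counts):
        x = np.asarray(counts, float)
        n = len(x)
        pairwise = np.abs(x[:, None] - x[None, :]).sum() / (2 * n * n * x.mean())
        assert gini(counts) == pytest.approx(pairwise, abs=1e-9)


class TestProfiles:
    def test_vertex_and_cluster_levels(self, toy_repertoire):
        net = build_network(toy_repertoire)
        v = diversity_profile(toy_repertoire, net, level="vertex")
        assert v.richness == 3
        assert v.shannon == pytest.approx(shannon([5, 2, 7]))
        c = diversity_profile(toy_repertoire, net, level="cluster")
        assert c.richness == 2
        assert c.shannon == pytest.approx(math.log(2))

    def test_single_clonotype_all_zero(self):
        rep = make_repertoire({"ACGT": 9})
        net = build_network(rep)
        for level in ("vertex", "cluster"):
            p = diversity_profile(rep, net, level=level)
            assert (p.shannon, p.gini_simpson, p.gini) == (0.0, 0.0, 0.0)

    def test_cluster_richness_never_exceeds_vertex_richness(self):
        rng = np.random.default_rng(3)
        from .conftest import random_sequences

        counts = {s: int(rng.integers(1, 9)) for s in random_sequences(rng, 70)}
        rep = make_repertoire(counts)
        net = build_network(rep)
        v = diversity_profile(rep, net, "vertex")
        c = diversity_profile(rep, net, "cluster")
        assert c.richness <= v.richness
        if not net.edges:
            assert c.richness == v.richness

    def test_empty_network_is_an_error(self):
        rep = Repertoire("e", [])
        with pytest.raises(EmptyRepertoireError):
            diversity_profile(rep, build_network(rep))


def _profile(sample_id, sh, level="vertex"):
    from bcrnet.diversity import DiversityProfile

    return DiversityProfile(
        sample_id=sample_id, level=level, richness=10, shannon=sh,
        gini_simpson=0.5, gini=0.3, total_reads=100,
    )


class TestNormalization:
    def test_ratio_to_healthy_mean(self):
        patient = [_profile("p", 1.5)]
        healthy = [_profile("h1", 2.0), _profile("h2", 4.0)]
        (out,) = normalize_to_healthy(patient, healthy)
        assert out.normalized_shannon == pytest.approx(0.5)

    def test_healthy_self_normalization_mean_is_one(self):
        healthy = [_profile(f"h{i}", sh) for i, sh in enumerate([1.0, 2.0, 3.5, 4.1])]
        out = normalize_to_healthy(healthy, healthy)
        assert np.mean([p.normalized_shannon for p in out]) == pytest.approx(1.0)
        assert np.mean([p.normalized_gini for p in out]) == pytest.approx(1.0)

    def test_single_volunteer_equal_to_patient(self):
        (out,) = normalize_to_healthy([_profile("p", 2.2)], [_profile("h", 2.2)])
        assert out.normalized_shannon == pytest.approx(1.0)

    def test_zero_healthy_mean_rejected(self):
        with pytest.raises(DegenerateDataError):
            normalize_to_healthy([_profile("p", 1.0)], [_profile("h", 0.0)])

    def test_empty_healthy_rejected(self):
        with pytest.raises(DegenerateDataError):
            normalize_to_healthy([_profile("p", 1.0)], [])


class TestDeltaSdi:
    def test_subtraction(self):
        assert delta_sdi({"TP2": 0.3, "TP3": 0.8}) == pytest.approx(0.5)

    def test_equal_timepoints(self):
        assert delta_sdi({"TP2": 0.6, "TP3": 0.6}) == 0.0

    def test_missing_timepoint_gives_marker(self):
        assert delta_sdi({"TP2": 0.3}) is None
        assert delta_sdi({"TP3": 0.3}) is None


class TestVGeneUsage:
    def _rep(self):
        return Repertoire(
            "s",
            [
                Clonotype("AAA", 60, v_gene="IGKV1-5"),
                Clonotype("CCC", 40, v_gene="IGKV3-20"),
            ],
        )

    def test_fractions_and_no_abnormal(self):
        df = v_gene_usage(self._rep(), {"IGKV1-5", "IGKV3-20"})
        assert sorted(df["fraction"]) == [pytest.approx(0.4), pytest.approx(0.6)]
        assert df.attrs["n_abnormal"] == 0

    def test_gene_absent_from_pool_flagged(self):
        df = v_gene_usage(self._rep(), {"IGKV1-5"})
        flagged = df[df["abnormal"]]
        assert list(flagged["v_gene"]) == ["IGKV3-20"]

    def test_empty_pool_flags_everything(self):
        df = v_gene_usage(self._rep(), set())
        assert df["abnormal"].all()
        assert df.attrs["n_abnormal"] == 2


class TestRarefaction:
    def test_full_depth_is_identity(self):
        counts = [5, 2, 7]
        assert list(rarefy(counts, 14)) == counts

    def test_depth_above_total_rejected(self):
        with pytest.raises(ValidationError):
            rarefy([5, 2], 100)

    def test_downsampling_reduces_total(self):
        out = rarefy([100, 50, 25], 30, seed=1)
        assert out.sum() == 30
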
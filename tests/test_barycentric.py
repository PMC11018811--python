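"""Barycentric triangle geometry and organ-spanning classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import clonotrack as ct

from conftest import make_table, pooled_organs

triples = st.tuples(*([st.integers(min_value=0, max_value=50)] * 3)).filter(
    lambda c: sum(c) > 0
)


class TestCoordinates:
    def test_single_compartment_clone_sits_at_vertex(self):
        p = ct.barycentric_coordinates((10, 0, 0), (100, 100, 100))
        assert p.weights == (1.0, 0.0, 0.0)

    def test_equal_frequencies_hit_centroid(self):
        p = ct.barycentric_coordinates((5, 5, 20), (100, 100, 400))
        assert np.allclose(p.weights, 1 / 3)

    def test_hand_computed_frequency_weights(self):
        # f = (0.02, 0.02, 0.01) -> weights (0.4, 0.4, 0.2)
        p = ct.barycentric_coordinates((2, 2, 4), (100, 100, 400))
        assert np.allclose(p.weights, (0.4, 0.4, 0.2))
        assert p.size == pytest.approx(0.05 / 3)

    def test_raw_mode_uses_counts(self):
        p = ct.barycentric_coordinates((2, 2, 4), (100, 100, 400),
                                       normalization="raw")
        assert np.allclose(p.weights, (0.25, 0.25, 0.5))

    def test_all_zero_counts_undefined(self):
        with pytest.raises(ct.UndefinedStatisticError):
            ct.barycentric_coordinates((0, 0, 0), (10, 10, 10))

    def test_positive_count_at_zero_depth_inconsistent(self):
        with pytest.raises(ct.ConfigError):
            ct.barycentric_coordinates((1, 0, 0), (0, 10, 10))

    @given(triples, st.permutations([0, 1, 2]))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_permutation_equivariance(self, counts, perm):
        depths = (100, 200, 400)
        base = ct.barycentric_coordinates(counts, depths).weights
        permuted = ct.barycentric_coordinates(
            tuple(counts[i] for i in perm), tuple(depths[i] for i in perm)
        ).weights
        assert np.allclose([base[i] for i in perm], permuted)

    @given(triples, st.integers(min_value=2, max_value=20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_depth_rescaling_invariance_in_frequency_mode(self, counts, factor):
        # deeper sequencing of one compartment must not move the point
        d1 = (100, 100, 100)
        d2 = (100 * factor, 100, 100)
        c2 = (counts[0] * factor, counts[1], counts[2])
        w1 = ct.barycentric_coordinates(counts, d1).weights
        w2 = ct.barycentric_coordinates(c2, d2).weights
        assert np.allclose(w1, w2)

    @given(triples)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_weights_sum_to_one_and_zero_iff_undetected(self, counts):
        p = ct.barycentric_coordinates(counts, (50, 100, 200))
        assert sum(p.weights) == pytest.approx(1.0, abs=1e-12)
        for c, w in zip(counts, p.weights):
            assert (w == 0) == (c == 0)


class TestClassification:
    def test_vertex_is_restricted(self):
        p = ct.barycentric_coordinates((10, 0, 0), (100, 100, 100))
        assert ct.classify_distribution(p) == "restricted(A)"

    def test_centroid_is_ubiquitous(self):
        p = ct.barycentric_coordinates((1, 1, 1), (100, 100, 100))
        assert ct.classify_distribution(p, 0.8) == "ubiquitous"

    def test_dominant_weight_is_biased(self):
        p = ct.BarycentricPoint(None, (0.85, 0.10, 0.05), 0.1, (85, 10, 5))
        assert ct.classify_distribution(p, 0.8) == "biased(A)"

    def test_threshold_must_exceed_third(self):
        p = ct.barycentric_coordinates((1, 1, 1), (10, 10, 10))
        with pytest.raises(ct.ConfigError):
            ct.classify_distribution(p, 1 / 3)


class TestTopClones:
    def test_full_set_when_n_equals_count(self):
        t = make_table({"a": 5, "b": 3, "c": 2})
        assert len(ct.top_clones(t, 3)) == 3

    def test_largest_clone_selected(self):
        t = make_table({"a": 3, "b": 5, "c": 3})
        top = ct.top_clones(t, 1)
        assert top.iloc[0] == 5

    def test_tie_at_cutoff_broken_lexicographically(self):
        t = make_table({"zz": 3, "aa": 3, "top": 5})
        counts = ct.counts_by_key(t)
        tied = sorted(k for k in counts.index if counts[k] == 3)
        top = ct.top_clones(t, 2)
        # both size-3 clones tie at the cutoff; the smaller key is included
        assert list(top) == [5, 3]
        assert top.index[1] == tied[0]
        ordered = ct.top_clones(t, 3)
        assert list(ordered.index[1:]) == tied

    def test_overlong_request_warns_and_returns_all(self):
        t = make_table({"a": 1, "b": 2})
        with pytest.warns(UserWarning):
            assert len(ct.top_clones(t, 10)) == 2


class TestBarycentricTable:
    def test_classes_and_geometry_on_fixture(self):
        a = make_table({"everywhere": 10, "only_a": 4}, sample_id="A")
        b = make_table({"everywhere": 10, "shared_bc": 2}, sample_id="B")
        c = make_table({"everywhere": 10, "shared_bc": 2}, sample_id="C")
        tri = ct.barycentric_table([a, b, c]).set_index("clone_key")
        by_class = tri["class"]
        assert (tri[["w_a", "w_b", "w_c"]].sum(axis=1) - 1).abs().max() < 1e-12
        assert sorted(by_class) == ["restricted(A)", "ubiquitous", "ubiquitous"]
        # triangle-plot coordinates stay inside the unit triangle
        assert tri["x"].between(0, 1).all()
        assert tri["y"].between(0, np.sqrt(3) / 2).all()

    def test_alloreactive_clones_span_organs_more_than_restricted(self, small_exp):
        pool = pooled_organs(small_exp, "poly")
        tri = ct.barycentric_table(
            [pool["spleen"], pool["liver"], pool["colon"]]
        ).set_index("clone_key")
        truth = small_exp.seeded_truths["poly"].clones.set_index("clone_key")
        tri = tri.join(truth["clone_class"], how="inner")
        frac = tri.groupby("clone_class")["class"].apply(
            lambda s: (s == "ubiquitous").mean()
        )
        assert frac["alloreactive"] > frac["tissue_restricted"]

    def test_requires_exactly_three_compartments(self):
        ts = [make_table({"a": 1}, sample_id=f"s{i}") for i in range(2)]
        with pytest.raises(ct.ConfigError):
            ct.barycentric_table(ts)
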
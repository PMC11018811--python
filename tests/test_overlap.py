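"""Morisita-family similarity, UMI-overlap fractions, sharing patterns."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import clonotrack as ct

from conftest import make_table, pooled_organs

count_maps = st.dictionaries(
    st.sampled_from([f"c{i}" for i in range(8)]),
    st.integers(min_value=1, max_value=30),
    min_size=1, max_size=8,
)


class TestMorisitaHorn:
    def test_identical_tables_give_one(self):
        t = make_table({"a": 7, "b": 2, "c": 1})
        assert ct.morisita_horn(t, t) == pytest.approx(1.0)

    def test_disjoint_tables_give_zero(self):
        x = make_table({"a": 5, "b": 5})
        y = make_table({"c": 5, "d": 5})
        assert ct.morisita_horn(x, y) == 0.0

    def test_hand_computed_value(self):
        # p=(.5,.25,.25), q=(.25,.25,.5): sum p^2 = sum q^2 = 0.375,
        # sum pq = 0.3125 -> 2*0.3125/0.75 = 5/6
        x = make_table({"c1": 2, "c2": 1, "c3": 1})
        y = make_table({"c1": 1, "c2": 1, "c3": 2})
        assert ct.morisita_horn(x, y) == pytest.approx(5.0 / 6.0)

    def test_empty_input_undefined(self):
        t = make_table({"a": 1})
        empty = ct.RepertoireTable(meta=t.meta, records=t.records.iloc[0:0])
        with pytest.raises(ct.UndefinedStatisticError):
            ct.morisita_horn(t, empty)

    @given(count_maps, count_maps, st.integers(min_value=2, max_value=7))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_symmetry_and_rescale_invariance(self, cx, cy, factor):
        x, y = make_table(cx, sample_id="x"), make_table(cy, sample_id="y")
        xs = make_table({k: v * factor for k, v in cx.items()}, sample_id="xs")
        mh = ct.morisita_horn(x, y)
        assert mh == pytest.approx(ct.morisita_horn(y, x))
        assert mh == pytest.approx(ct.morisita_horn(xs, y))
        assert -1e-12 <= mh <= 1 + 1e-12


class TestMorisitaClassical:
    def test_disjoint_is_zero(self):
        assert ct.morisita_classical(make_table({"a": 3, "b": 2}),
                                     make_table({"c": 3, "d": 2})) == 0.0

    def test_large_identical_near_one(self):
        t = make_table({"a": 50, "b": 25, "c": 25})
        assert 0.9 <= ct.morisita_classical(t, t) <= 1.1

    def test_small_sample_exceeds_one_with_warning(self):
        # x=y=[2,1,1]: lam = 2/12, C = 2*6/((1/3)*16) = 2.25
        t = make_table({"a": 2, "b": 1, "c": 1})
        with pytest.warns(UserWarning, match="small-sample"):
            value = ct.morisita_classical(t, t)
        assert value == pytest.approx(2.25)

    def test_undefined_below_two_molecules(self):
        with pytest.raises(ct.UndefinedStatisticError):
            ct.morisita_classical(make_table({"a": 1}), make_table({"a": 5}))


class TestUmiOverlapFraction:
    def test_directional_and_pooled_hand_values(self):
        x = make_table({"c1": 5, "c2": 5})
        y = make_table({"c1": 3, "c3": 7})
        assert ct.umi_overlap_fraction(x, y, "directional") == pytest.approx(0.5)
        assert ct.umi_overlap_fraction(x, y, "pooled") == pytest.approx(0.4)

    def test_superset_gives_one(self):
        x = make_table({"a": 2, "b": 3})
        y = make_table({"a": 1, "b": 1, "c": 9})
        assert ct.umi_overlap_fraction(x, y, "directional") == 1.0

    def test_self_overlap_is_one(self):
        t = make_table({"a": 2, "b": 3})
        assert ct.umi_overlap_fraction(t, t) == 1.0


class TestBruteForceEquivalence:
    """Statistics agree with a per-UMI materialization oracle."""

    @staticmethod
    def umi_objects(table):
        counts = ct.counts_by_key(table)
        return [k for k, n in counts.items() for _ in range(int(n))]

    @given(count_maps, count_maps)
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_directional_fraction(self, cx, cy):
        x, y = make_table(cx, sample_id="x"), make_table(cy, sample_id="y")
        ux, uy = self.umi_objects(x), self.umi_objects(y)
        oracle = sum(u in set(uy) for u in ux) / len(ux)
        assert ct.umi_overlap_fraction(x, y, "directional") == pytest.approx(oracle)

    @given(count_maps, count_maps)
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_morisita_horn_from_umi_multisets(self, cx, cy):
        from collections import Counter
        x, y = make_table(cx, sample_id="x"), make_table(cy, sample_id="y")
        ux, uy = Counter(self.umi_objects(x)), Counter(self.umi_objects(y))
        keys = sorted(set(ux) | set(uy))
        p = np.array([ux[k] for k in keys]) / sum(ux.values())
        q = np.array([uy[k] for k in keys]) / sum(uy.values())
        oracle = 2 * (p * q).sum() / ((p * p).sum() + (q * q).sum())
        assert ct.morisita_horn(x, y) == pytest.approx(oracle)


class TestPairwiseAndSharing:
    def test_identical_tables_all_ones(self):
        ts = [make_table({"a": 3, "b": 1}, sample_id=f"s{i}") for i in range(3)]
        mat = ct.pairwise_overlap(ts, "morisita_horn").values.to_numpy()
        assert np.allclose(mat, 1.0)

    def test_zeros_exactly_where_disjoint(self):
        x = make_table({"a": 3}, sample_id="x")
        y = make_table({"b": 3}, sample_id="y")
        z = make_table({"a": 1, "b": 1}, sample_id="z")
        mat = ct.pairwise_overlap([x, y, z], "morisita_horn").values
        assert mat.loc["x", "y"] == 0.0
        assert mat.loc["x", "z"] > 0 and mat.loc["y", "z"] > 0

    def test_spleen_liver_most_similar_in_simulation(self, small_exp):
        pool = pooled_organs(small_exp, "poly")
        mh = ct.pairwise_overlap(
            [pool["spleen"], pool["liver"], pool["colon"]], "morisita_horn"
        ).values
        sp_li = mh.iloc[0, 1]
        assert sp_li > mh.iloc[0, 2] and sp_li > mh.iloc[1, 2]

    def test_disjoint_sharing_patterns_are_singletons(self):
        x = make_table({"a": 3}, sample_id="x")
        y = make_table({"b": 4}, sample_id="y")
        s = ct.sharing_summary([x, y]).set_index("pattern")
        assert set(s.index) == {"x", "y"}
        assert s["total_mass"].sum() == 7

    def test_identical_sharing_pattern_is_full(self):
        ts = [make_table({"a": 3, "b": 1}, sample_id=f"s{i}") for i in range(3)]
        s = ct.sharing_summary(ts)
        assert list(s["pattern"]) == ["s0+s1+s2"]
        assert s["n_clonotypes"].iloc[0] == 2

    def test_triple_pattern_counted_once(self):
        x = make_table({"shared": 1, "x": 1}, sample_id="x")
        y = make_table({"shared": 2, "y": 1}, sample_id="y")
        z = make_table({"shared": 3}, sample_id="z")
        s = ct.sharing_summary([x, y, z]).set_index("pattern")
        assert s.loc["x+y+z", "n_clonotypes"] == 1
        assert s["n_clonotypes"].sum() == 3  # union of keys
        assert s["total_mass"].sum() == 8

    def test_circos_links_fractions(self):
        x = make_table({"c1": 5, "c2": 5}, sample_id="x")
        y = make_table({"c1": 3, "c3": 7}, sample_id="y")
        links = ct.circos_links([x, y])
        row = links.iloc[0]
        assert row["source_fraction"] == pytest.approx(0.5)
        assert row["target_fraction"] == pytest.approx(0.3)
        assert row["shared_mass"] == 8
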
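"""The synthetic graft-expansion-and-seeding generator."""

import numpy as np
import pytest

import clonotrack as ct
from clonotrack.simulate import (
    ORGANS,
    simulate_donor_repertoire,
    simulate_expansion,
    simulate_sc_table,
    simulate_seeding,
)

from conftest import SMALL_CONFIG


def small_config(**kw):
    return ct.SimulationConfig(**{**SMALL_CONFIG, "seed": 1, **kw})


class TestDonorRepertoire:
    def test_all_clone_keys_distinct(self):
        cfg = small_config(n_clones=1000)
        _, truth = simulate_donor_repertoire(cfg)
        assert truth.clones["clone_key"].is_unique
        assert len(truth.clones) == 1000

    def test_class_fractions_within_binomial_bands(self):
        cfg = small_config(n_clones=4000, allo_fraction=0.1)
        _, truth = simulate_donor_repertoire(cfg)
        n_allo = (truth.clones["clone_class"] == "alloreactive").sum()
        sd = np.sqrt(4000 * 0.1 * 0.9)
        assert abs(n_allo - 400) < 4 * sd

    def test_same_seed_byte_identical(self, tmp_path):
        t1, _ = simulate_donor_repertoire(small_config())
        t2, _ = simulate_donor_repertoire(small_config())
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        ct.write_clonotype_table(t1, p1)
        ct.write_clonotype_table(t2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_restricted_clones_prefer_designated_segments(self):
        _, truth = simulate_donor_repertoire(small_config(n_clones=3000))
        biased = set(ct.DEFAULT_SEGMENT_SET)
        by_class = truth.clones.groupby("clone_class")["v_call"].apply(
            lambda s: s.isin(biased).mean()
        )
        assert by_class["tissue_restricted"] > 0.5 > by_class["bystander"]

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ct.ConfigError):
            small_config(allo_fraction=0.9, colon_biased_fraction=0.2).validate()
        with pytest.raises(ct.ConfigError):
            small_config(clone_size_law="zipf").validate()

    def test_total_umis_equals_configured_depth(self):
        table, _ = simulate_donor_repertoire(small_config())
        assert table.total_umis == SMALL_CONFIG["donor_depth"]


class TestExpansion:
    def test_zero_noise_poly_is_identity(self):
        cfg = small_config(poly_noise=0.0)
        donor, truth = simulate_donor_repertoire(cfg)
        _, after = simulate_expansion(donor, truth, "poly", cfg)
        assert np.allclose(after.clones["proportion"], truth.clones["proportion"])

    def test_allo_mode_depletes_restricted_mass(self):
        cfg = small_config()
        donor, truth = simulate_donor_repertoire(cfg)
        _, after = simulate_expansion(donor, truth, "allo", cfg)
        def mass(t, cls):
            c = t.clones
            return c.loc[c["clone_class"] == cls, "proportion"].sum()
        assert mass(after, "tissue_restricted") < mass(truth, "tissue_restricted")
        assert mass(after, "alloreactive") > mass(truth, "alloreactive")

    def test_unknown_mode_rejected(self):
        cfg = small_config()
        donor, truth = simulate_donor_repertoire(cfg)
        with pytest.raises(ct.ConfigError):
            simulate_expansion(donor, truth, "autologous", cfg)


class TestSeeding:
    def test_every_organ_table_at_configured_depth(self, small_exp):
        for (rid, organ), table in small_exp.seeded["poly"].items():
            assert table.total_umis == small_exp.config.organ_depths[organ]

    def test_restricted_clones_concentrate_in_colon(self, small_exp):
        truth = small_exp.seeded_truths["poly"].clones
        restricted = truth[truth["clone_class"] == "tissue_restricted"]
        assert restricted["freq_colon"].sum() > 5 * restricted["freq_spleen"].sum()

    def test_recipients_share_selection(self, small_exp):
        # same organ across recipients: independent draws from shared weights
        for organ in ORGANS:
            pair = [small_exp.seeded["allo"][(f"r{r}", organ)] for r in (1, 2)]
            assert ct.morisita_horn(*pair) > 0.5

    def test_single_class_uniform_weights_is_plain_multinomial(self):
        cfg = small_config(
            allo_fraction=1e-9, colon_biased_fraction=1e-9,
            in_vivo_gain=1.0, in_vivo_gain_sd=0.0, n_recipients=1,
        )
        donor, truth = simulate_donor_repertoire(cfg)
        product, truth2 = simulate_expansion(donor, truth, "poly", cfg)
        tables, seeded_truth = simulate_seeding(product, truth2, cfg)
        for organ in ORGANS:
            expected = seeded_truth.clones[f"freq_{organ}"]
            assert np.allclose(expected, truth2.clones["proportion"])


class TestScTable:
    def test_no_defects_all_cells_survive(self, tmp_path):
        cfg = small_config(sc_defect_fraction=0.0)
        donor, truth = simulate_donor_repertoire(cfg)
        sc = simulate_sc_table(donor, truth, 400, cfg)
        path = tmp_path / "contigs.csv"
        sc.to_csv(path, index=False)
        pc = ct.read_sc_contigs(path, "s")
        assert pc.total_cells == 400

    def test_defect_fraction_matches_survival(self, tmp_path):
        cfg = small_config(sc_defect_fraction=0.2)
        donor, truth = simulate_donor_repertoire(cfg)
        n = 5000
        sc = simulate_sc_table(donor, truth, n, cfg)
        path = tmp_path / "contigs.csv"
        sc.to_csv(path, index=False)
        pc = ct.read_sc_contigs(path, "s")
        sd = np.sqrt(n * 0.2 * 0.8)
        assert abs(pc.total_cells - 0.8 * n) < 4 * sd

    def test_surviving_cells_recover_clone_proportions(self, tmp_path):
        cfg = small_config(sc_defect_fraction=0.1)
        donor, truth = simulate_donor_repertoire(cfg)
        n = 4000
        sc = simulate_sc_table(donor, truth, n, cfg)
        path = tmp_path / "contigs.csv"
        sc.to_csv(path, index=False)
        pc = ct.read_sc_contigs(path, "s")
        # the biggest bulk clone's cell share should match its UMI share
        top = donor.records.nlargest(1, "umi_count").iloc[0]
        bulk_share = top["umi_count"] / donor.total_umis
        cells = pc.clones
        match = cells[cells["cdr3b_nt"] == top["cdr3_nt"]]["cell_count"].sum()
        cell_share = match / pc.total_cells
        se = np.sqrt(bulk_share * (1 - bulk_share) / pc.total_cells)
        assert abs(cell_share - bulk_share) < 4 * se + 1e-3


def test_full_experiment_deterministic(small_exp, tmp_path):
    again = ct.simulate_experiment(ct.SimulationConfig(seed=1, **SMALL_CONFIG))
    for mode in ("poly", "allo"):
        a = small_exp.seeded[mode][("r2", "liver")]
        b = again.seeded[mode][("r2", "liver")]
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        ct.write_clonotype_table(a, pa)
        ct.write_clonotype_table(b, pb)
        assert pa.read_bytes() == pb.read_bytes()
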
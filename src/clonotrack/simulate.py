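"""Synthetic graft-expansion-and-seeding experiments with ground truth.

The generator emulates the statistical structure of an adoptive-transfer
clonal-tracking study: a heavy-tailed donor Treg repertoire is expanded
in vitro either polyclonally (diversity-preserving lognormal jitter) or
allo-selectively (a small alloreactive subset gains a large expansion
advantage while gut-responsive clones are depleted, narrowing the
repertoire); the product then seeds spleen, liver and colon of several
recipients, with alloreactive clones spreading near-uniformly across
organs and a low-frequency tissue-restricted subset - carrying
designated colon-enriched V-beta segments - homing preferentially to
the colon. Every emitted repertoire is a multinomial UMI sample at a
configured depth, and every clone carries a ground-truth class label so
pipeline stages can be tested for parameter recovery.

All draws flow from one integer seed through ``numpy`` generators, so a
fixed configuration reproduces byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .errors import ConfigError
from .io import RepertoireTable, SampleMeta

ORGANS = ("spleen", "liver", "colon")
CLASSES = ("alloreactive", "tissue_restricted", "bystander")

TRBV_SEGMENTS = (
    "TRBV1", "TRBV2", "TRBV3", "TRBV4", "TRBV5",
    "TRBV12-1", "TRBV12-2", "TRBV13-1", "TRBV13-2", "TRBV13-3",
    "TRBV14", "TRBV15", "TRBV16", "TRBV17", "TRBV19",
    "TRBV20", "TRBV23", "TRBV26", "TRBV29", "TRBV31",
)
TRBJ_SEGMENTS = (
    "TRBJ1-1", "TRBJ1-2", "TRBJ1-3", "TRBJ1-4", "TRBJ1-5",
    "TRBJ2-1", "TRBJ2-2", "TRBJ2-3", "TRBJ2-4", "TRBJ2-5", "TRBJ2-7",
)
TRAV_SEGMENTS = (
    "TRAV1", "TRAV2", "TRAV3-1", "TRAV4-2", "TRAV6-1", "TRAV7-2",
    "TRAV8-1", "TRAV9-1", "TRAV10", "TRAV12-1", "TRAV13-1", "TRAV14-1",
    "TRAV16", "TRAV16D-DV11", "TRAV19", "TRAV21-DV12",
)
TRAJ_SEGMENTS = (
    "TRAJ2", "TRAJ5", "TRAJ9", "TRAJ12", "TRAJ15", "TRAJ18", "TRAJ21",
    "TRAJ23", "TRAJ26", "TRAJ27", "TRAJ31", "TRAJ33", "TRAJ37", "TRAJ40",
    "TRAJ43", "TRAJ49", "TRAJ52", "TRAJ56", "TRAJ57", "TRAJ58",
)


@dataclass
class SimulationConfig:
    """Parameters of one synthetic experiment.

    Clone sizes follow a power law with tail exponent ``power_alpha``
    (or a lognormal). ``allo_fraction`` of clones are alloreactive and
    gain a factor ``allo_gain`` under allo-selective expansion;
    ``colon_biased_fraction`` of the remainder are tissue-restricted,
    colon-tropic and preferentially carry ``colon_biased_segments``.
    Polyclonal expansion multiplies proportions by
    ``exp(N(0, poly_noise))``. Organ tables are multinomial draws of
    exactly ``organ_depths[organ]`` UMIs.
    """

    n_clones: int = 5000
    clone_size_law: str = "power_law"  # or "log_normal"
    power_alpha: float = 1.5
    lognorm_mu: float = 0.0
    lognorm_sigma: float = 1.5
    allo_fraction: float = 0.05
    allo_gain: float = 8.0
    allo_gain_sd: float = 1.5  # lognormal spread of per-clone allo gains
    poly_noise: float = 0.2
    n_recipients: int = 3
    donor_depth: int = 30000
    product_depth: int = 30000
    organ_depths: dict = field(
        default_factory=lambda: {"spleen": 20000, "liver": 20000, "colon": 20000}
    )
    seeding_weights: dict = field(
        default_factory=lambda: {
            "alloreactive": {"spleen": 1 / 3, "liver": 1 / 3, "colon": 1 / 3},
            "tissue_restricted": {"spleen": 0.05, "liver": 0.05, "colon": 0.90},
            "bystander": None,  # depth-proportional
        }
    )
    colon_biased_segments: tuple = ("TRBV12-1", "TRBV12-2", "TRBV26")
    colon_biased_fraction: float = 0.03
    biased_segment_prob: float = 0.8
    restricted_size_factor: float = 0.25  # tissue-restricted clones start small
    in_vivo_gain: float = 8.0  # host-driven expansion of alloreactive clones
    in_vivo_gain_sd: float = 1.5
    recipient_weight_jitter: float = 0.0  # lognormal SD of per-recipient weights
    sc_defect_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_clones < 1:
            raise ConfigError("n_clones must be >= 1")
        if not 0 < self.allo_fraction < 1:
            raise ConfigError("allo_fraction must lie in (0, 1)")
        if self.allo_fraction + self.colon_biased_fraction >= 1:
            raise ConfigError("allo_fraction + colon_biased_fraction must be < 1")
        if self.allo_gain <= 1:
            raise ConfigError("allo_gain must exceed 1")
        if self.in_vivo_gain < 1:
            raise ConfigError("in_vivo_gain must be >= 1")
        if self.allo_gain_sd < 0 or self.in_vivo_gain_sd < 0:
            raise ConfigError("gain SDs must be >= 0")
        if not 0 < self.restricted_size_factor <= 1:
            raise ConfigError("restricted_size_factor must lie in (0, 1]")
        if self.poly_noise < 0:
            raise ConfigError("poly_noise must be >= 0")
        if self.clone_size_law not in ("power_law", "log_normal"):
            raise ConfigError(f"unknown clone_size_law {self.clone_size_law!r}")
        if set(self.organ_depths) != set(ORGANS):
            raise ConfigError(f"organ_depths must cover exactly {ORGANS}")
        if any(d < 0 for d in self.organ_depths.values()):
            raise ConfigError("organ depths must be non-negative")
        for cls in ("alloreactive", "tissue_restricted"):
            w = self.seeding_weights.get(cls)
            if w is None:
                continue
            vals = np.array([w[o] for o in ORGANS], dtype=float)
            if (vals < 0).any() or not np.isclose(vals.sum(), 1.0):
                raise ConfigError(f"seeding weights for {cls} must be a "
                                  "non-negative distribution over organs")
        if not 0 <= self.sc_defect_fraction < 1:
            raise ConfigError("sc_defect_fraction must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Per-clone truth ledger.

    ``clones`` has one row per clone: identity columns (beta and alpha
    chains), ``clone_key`` (the nucleotide-level key used throughout the
    pipeline), ``clone_class``, and ``proportion`` - the true proportion
    in the repertoire this truth accompanies (donor, or a product).
    Seeding adds ``freq_<organ>`` expected-frequency columns.
    """

    clones: pd.DataFrame
    stage: str = "donor"


def _unique_cdr3(rng: np.random.Generator, n: int, taken: set | None = None
                 ) -> list[str]:
    """Random in-frame CDR3 nucleotide strings, collision-checked."""
    taken = set() if taken is None else set(taken)
    bases = np.array(list("ACGT"))
    out: list[str] = []
    while len(out) < n:
        length = 3 * int(rng.integers(10, 16))
        s = "".join(bases[rng.integers(0, 4, size=length)])
        if s not in taken:
            taken.add(s)
            out.append(s)
    return out


def _translate(nt: str) -> str:
    return str(Seq(nt).translate())


def simulate_donor_repertoire(config: SimulationConfig
                              ) -> tuple[RepertoireTable, GroundTruth]:
    """Draw the fresh donor repertoire and its truth ledger."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_clones

    if config.clone_size_law == "power_law":
        # Pareto with tail index alpha: P(size > s) ~ s^-alpha
        sizes = 1.0 + rng.pareto(config.power_alpha, size=n)
    else:
        sizes = rng.lognormal(config.lognorm_mu, config.lognorm_sigma, size=n)

    u = rng.random(n)
    clone_class = np.where(
        u < config.allo_fraction,
        "alloreactive",
        np.where(u < config.allo_fraction + config.colon_biased_fraction,
                 "tissue_restricted", "bystander"),
    )
    # tissue-restricted clones enter the graft at low frequency: they are
    # antigen-naive toward the culture stimulus and small in the spleen pool
    sizes = np.where(clone_class == "tissue_restricted",
                     sizes * config.restricted_size_factor, sizes)
    proportions = sizes / sizes.sum()

    biased = np.array(config.colon_biased_segments)
    other_v = np.array([v for v in TRBV_SEGMENTS if v not in set(biased)])
    v_call = rng.choice(TRBV_SEGMENTS, size=n)
    restricted = clone_class == "tissue_restricted"
    carry = rng.random(n) < config.biased_segment_prob
    v_call[restricted & carry] = rng.choice(biased, size=int((restricted & carry).sum()))
    v_call[restricted & ~carry] = rng.choice(other_v, size=int((restricted & ~carry).sum()))

    cdr3b = _unique_cdr3(rng, n)
    cdr3a = _unique_cdr3(rng, n, taken=set(cdr3b))
    clones = pd.DataFrame(
        {
            "chain": "TRB",
            "v_call": v_call,
            "j_call": rng.choice(TRBJ_SEGMENTS, size=n),
            "cdr3_nt": cdr3b,
            "cdr3_aa": [_translate(s) for s in cdr3b],
            "tra_v": rng.choice(TRAV_SEGMENTS, size=n),
            "tra_j": rng.choice(TRAJ_SEGMENTS, size=n),
            "cdr3a_nt": cdr3a,
            "clone_class": clone_class,
            "proportion": proportions,
        }
    )
    clones["clone_key"] = (
        clones["chain"] + "|" + clones["v_call"] + "|" + clones["j_call"]
        + "|" + clones["cdr3_nt"]
    )
    truth = GroundTruth(clones=clones, stage="donor")
    meta = SampleMeta("donor_fresh", organ="donor", treatment="fresh",
                      setting="donor_product")
    table = _sample_table(truth, config.donor_depth, meta, rng)
    return table, truth


def _sample_table(truth: GroundTruth, depth: int, meta: SampleMeta,
                  rng: np.random.Generator) -> RepertoireTable:
    """Multinomial UMI sample of ``depth`` molecules from true proportions."""
    p = truth.clones["proportion"].to_numpy()
    counts = rng.multinomial(int(depth), p / p.sum())
    kept = counts > 0
    records = truth.clones.loc[kept, ["chain", "v_call", "j_call", "cdr3_nt",
                                      "cdr3_aa"]].copy()
    records["umi_count"] = counts[kept]
    return RepertoireTable(meta=meta, records=records.reset_index(drop=True))


def simulate_expansion(
    donor: RepertoireTable,
    truth: GroundTruth,
    mode: str,
    config: SimulationConfig,
) -> tuple[RepertoireTable, GroundTruth]:
    """Expand the donor repertoire in vitro.

    ``poly``: every clone's proportion is jittered by
    ``exp(N(0, poly_noise))`` and renormalized, preserving breadth.
    ``allo``: the same culture jitter, but each alloreactive clone draws
    its own expansion advantage from ``LogNormal(ln(allo_gain),
    allo_gain_sd)`` — antigen-driven selection is clone-specific and
    compounds over the culture, so a handful of allo clones come to
    dominate and the repertoire narrows — while tissue-restricted clones
    are depleted by ``1/allo_gain``.
    """
    if mode not in ("poly", "allo"):
        raise ConfigError(f"unknown expansion mode {mode!r}")
    rng = np.random.default_rng([config.seed, 1 if mode == "poly" else 2])
    clones = truth.clones.copy()
    p = clones["proportion"].to_numpy(dtype=float)
    jitter = np.exp(rng.normal(0.0, config.poly_noise, size=len(p)))
    p = p * jitter
    if mode == "allo":
        cls = clones["clone_class"].to_numpy()
        gains = np.exp(rng.normal(np.log(config.allo_gain), config.allo_gain_sd,
                                  size=len(p)))
        p = np.where(cls == "alloreactive", p * gains, p)
        p = np.where(cls == "tissue_restricted", p / config.allo_gain, p)
    clones["proportion"] = p / p.sum()
    new_truth = GroundTruth(clones=clones, stage=f"product_{mode}")
    meta = SampleMeta(f"product_{mode}", organ="donor", treatment=mode,
                      setting="donor_product")
    table = _sample_table(new_truth, config.product_depth, meta, rng)
    return table, new_truth


def _organ_weight_matrix(truth: GroundTruth, config: SimulationConfig,
                         rng: np.random.Generator) -> np.ndarray:
    """Per-clone, per-organ pre-normalization seeding weights.

    Each alloreactive clone carries an additional host-driven expansion
    factor ``LogNormal(ln(in_vivo_gain), in_vivo_gain_sd)`` applied in
    every organ: allo-antigens are ubiquitous in the MHC-mismatched
    host, so the same selected clones dominate all three organs — which
    is what narrows re-isolated repertoires relative to the graft and
    makes the dominant clonotypes organ-spanning.
    """
    depths = np.array([config.organ_depths[o] for o in ORGANS], dtype=float)
    depth_w = depths / depths.sum()
    rows = np.empty((len(truth.clones), len(ORGANS)))
    cls = truth.clones["clone_class"].to_numpy()
    for name in CLASSES:
        w = config.seeding_weights.get(name)
        vals = depth_w if w is None else np.array([w[o] for o in ORGANS])
        rows[cls == name] = vals
    n_allo = int((cls == "alloreactive").sum())
    gains = np.exp(rng.normal(np.log(config.in_vivo_gain),
                              config.in_vivo_gain_sd, size=n_allo))
    rows[cls == "alloreactive"] *= gains[:, None]
    # tissue-restricted clones respond to local colon antigens and expand
    # there, so the colon acquires its own dominant restricted clones
    n_restricted = int((cls == "tissue_restricted").sum())
    local = np.exp(rng.normal(np.log(config.in_vivo_gain),
                              config.in_vivo_gain_sd, size=n_restricted))
    colon_idx = ORGANS.index("colon")
    rows[cls == "tissue_restricted", colon_idx] *= local
    return rows * truth.clones["proportion"].to_numpy()[:, None]


def simulate_seeding(
    product: RepertoireTable,
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[dict, GroundTruth]:
    """Seed recipient organs from a product repertoire.

    Clone weights in each organ are the product proportion times the
    class-specific organ weight, renormalized; each recipient's organ
    table is an independent multinomial draw of the configured depth
    from those shared weights (an optional per-recipient lognormal
    jitter of the weights is available for robustness studies).

    Returns ``{(recipient_id, organ): RepertoireTable}`` and a truth
    ledger extended with expected per-organ frequencies.
    """
    if config.n_recipients < 1:
        raise ConfigError("n_recipients must be >= 1")
    mode = product.meta.treatment
    # in-vivo selection is drawn once per product: recipients share it
    selection_rng = np.random.default_rng(
        [config.seed, 5, 1 if mode == "poly" else 2]
    )
    base = _organ_weight_matrix(truth, config, selection_rng)
    clones = truth.clones.copy()
    for j, organ in enumerate(ORGANS):
        col = base[:, j]
        clones[f"freq_{organ}"] = col / col.sum() if col.sum() > 0 else 0.0
    out_truth = GroundTruth(clones=clones, stage=f"seeded_{mode}")

    tables: dict = {}
    for r in range(config.n_recipients):
        rid = f"r{r + 1}"
        rng = np.random.default_rng([config.seed, 3, 1 if mode == "poly" else 2, r])
        weights = base
        if config.recipient_weight_jitter > 0:
            weights = base * np.exp(
                rng.normal(0.0, config.recipient_weight_jitter, size=base.shape)
            )
        for j, organ in enumerate(ORGANS):
            depth = int(config.organ_depths[organ])
            meta = SampleMeta(
                sample_id=f"{mode}_{rid}_{organ}",
                organ=organ,
                recipient_id=rid,
                treatment=mode,
                setting="GvHD",
                replicate=rid,
            )
            if depth == 0:
                import warnings

                warnings.warn(f"zero depth for {meta.sample_id}: empty table",
                              stacklevel=2)
                records = clones.iloc[0:0][["chain", "v_call", "j_call", "cdr3_nt",
                                            "cdr3_aa"]].assign(umi_count=[])
                tables[(rid, organ)] = RepertoireTable(meta=meta, records=records)
                continue
            w = weights[:, j]
            counts = rng.multinomial(depth, w / w.sum())
            kept = counts > 0
            records = clones.loc[kept, ["chain", "v_call", "j_call", "cdr3_nt",
                                        "cdr3_aa"]].copy()
            records["umi_count"] = counts[kept]
            tables[(rid, organ)] = RepertoireTable(
                meta=meta, records=records.reset_index(drop=True)
            )
    return tables, out_truth


def simulate_sc_table(
    table: RepertoireTable,
    truth: GroundTruth,
    cells: int,
    config: SimulationConfig,
    barcode_prefix: str = "CELL",
) -> pd.DataFrame:
    """Emit a 10x-style contig table of paired-chain cells for one sample.

    Cells are drawn from the sample's clone proportions; each intact
    cell contributes one TRA and one TRB contig row whose beta chain
    matches the bulk clonotype. A fraction ``sc_defect_fraction`` of
    cells is made defective (missing alpha, missing beta, or doublet
    alpha) to exercise the pairing filter.
    """
    if cells < 1:
        raise ConfigError("cells must be >= 1")
    rng = np.random.default_rng([config.seed, 4])
    lookup = truth.clones.set_index("clone_key")
    keys = (
        table.records["chain"] + "|" + table.records["v_call"] + "|"
        + table.records["j_call"] + "|" + table.records["cdr3_nt"]
    )
    p = table.records["umi_count"].to_numpy(dtype=float)
    draw = rng.multinomial(cells, p / p.sum())
    rows = []
    cell_idx = 0
    n_spare = max(16, int(cells * config.sc_defect_fraction))
    spare_cdr3a = iter(_unique_cdr3(rng, n_spare, taken=set(lookup["cdr3a_nt"])))
    for key, n_cells in zip(keys, draw):
        if n_cells == 0:
            continue
        info = lookup.loc[key]
        for _ in range(int(n_cells)):
            barcode = f"{barcode_prefix}{cell_idx:07d}-1"
            cell_idx += 1
            defect = None
            if rng.random() < config.sc_defect_fraction:
                defect = ("missing_tra", "missing_trb", "double_tra")[
                    int(rng.integers(3))
                ]
            contigs = []
            if defect != "missing_tra":
                contigs.append(("TRA", info["tra_v"], info["tra_j"],
                                info["cdr3a_nt"]))
            if defect == "double_tra":
                contigs.append(("TRA", str(rng.choice(TRAV_SEGMENTS)),
                                str(rng.choice(TRAJ_SEGMENTS)), next(spare_cdr3a)))
            if defect != "missing_trb":
                contigs.append(("TRB", info["v_call"], info["j_call"],
                                info["cdr3_nt"]))
            for chain, v, j, nt in contigs:
                rows.append(
                    {
                        "barcode": barcode,
                        "is_cell": "True",
                        "high_confidence": "True",
                        "chain": chain,
                        "v_gene": v,
                        "j_gene": j,
                        "cdr3_nt": nt,
                        "cdr3": _translate(nt),
                        "productive": "True",
                        "umis": 1,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class SimulatedExperiment:
    """Bundle of one complete synthetic experiment."""

    config: SimulationConfig
    donor: RepertoireTable
    donor_truth: GroundTruth
    products: dict  # mode -> RepertoireTable
    product_truths: dict  # mode -> GroundTruth
    seeded: dict  # mode -> {(recipient, organ): RepertoireTable}
    seeded_truths: dict  # mode -> GroundTruth


def simulate_experiment(config: SimulationConfig | None = None) -> SimulatedExperiment:
    """Run the full generative model: donor -> poly/allo products ->
    three-organ seeding in every recipient."""
    config = config or SimulationConfig()
    donor, donor_truth = simulate_donor_repertoire(config)
    products, product_truths, seeded, seeded_truths = {}, {}, {}, {}
    for mode in ("poly", "allo"):
        products[mode], product_truths[mode] = simulate_expansion(
            donor, donor_truth, mode, config
        )
        seeded[mode], seeded_truths[mode] = simulate_seeding(
            products[mode], product_truths[mode], config
        )
    return SimulatedExperiment(
        config=config,
        donor=donor,
        donor_truth=donor_truth,
        products=products,
        product_truths=product_truths,
        seeded=seeded,
        seeded_truths=seeded_truths,
    )
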
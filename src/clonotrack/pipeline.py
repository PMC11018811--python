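"""End-to-end pipeline: simulate (or load) -> analyze -> report.

A run is driven by a flat YAML/dict configuration with a ``simulation``
(or ``sample_sheet``) input section and per-stage switches. All enabled
stages are validated before any stage executes (fail-fast); every output
file is listed in a manifest with a SHA-256 checksum, so a rerun with
the same configuration and seed can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import barycentric, diversity, overlap, segment_usage, tsea
from .errors import ConfigError
from .io import counts_by_key, pool_samples, read_airr, read_mixcr_tsv, \
    read_sample_sheet, write_clonotype_table
from .simulate import ORGANS, SimulationConfig, simulate_experiment

log = logging.getLogger("clonotrack")

STAGES = ("diversity", "overlap", "barycentric", "tsea", "usage")

DEFAULT_STAGE_PARAMS = {
    "diversity": {"n_reps": 25},
    "overlap": {"method": "morisita_horn"},
    "barycentric": {"normalization": "frequency", "dominance_threshold": 0.9},
    "tsea": {"n_perm": 999, "alternative": "toward_top"},
    "usage": {"weighting": "by_clone",
              "segment_set": sorted(segment_usage.DEFAULT_SEGMENT_SET)},
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: run configuration must be a mapping")
    return cfg


def validate_config(cfg: dict) -> dict:
    """Fail-fast validation of the whole run before any stage executes.

    Returns a normalized copy with stage defaults filled in.
    """
    cfg = dict(cfg)
    has_sim = "simulation" in cfg
    has_sheet = "sample_sheet" in cfg
    if has_sim == has_sheet:
        raise ConfigError("exactly one of 'simulation' or 'sample_sheet' required")
    if has_sim:
        sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
        unknown = set(cfg["simulation"] or {}) - sim_fields
        if unknown:
            raise ConfigError(f"unknown simulation parameters {sorted(unknown)}")
        SimulationConfig(**(cfg["simulation"] or {})).validate()
    stages = cfg.setdefault("stages", {})
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages {sorted(unknown)}")
    for name in STAGES:
        params = dict(DEFAULT_STAGE_PARAMS[name])
        user = stages.get(name, {}) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"stage {name}: parameters must be a mapping")
        bad = set(user) - set(params) - {"enabled"}
        if bad:
            raise ConfigError(f"stage {name}: unknown parameters {sorted(bad)}")
        params.update(user)
        params.setdefault("enabled", True)
        stages[name] = params
    if stages["tsea"]["enabled"]:
        if stages["tsea"]["n_perm"] < 99:
            raise ConfigError("tsea: n_perm must be >= 99")
        if has_sheet and not cfg.get("graft_sample"):
            raise ConfigError("tsea enabled but no graft reference: set "
                              "'graft_sample' to a sample_id of the sheet")
    if stages["barycentric"]["enabled"]:
        t = stages["barycentric"]["dominance_threshold"]
        if not 1 / 3 < t <= 1:
            raise ConfigError("barycentric: dominance_threshold must be in (1/3, 1]")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _emit(manifest: list, stage: str, path: Path) -> None:
    manifest.append({"stage": stage, "path": path.name, "sha256": _sha256(path)})
    log.info("%s -> %s", stage, path.name)


def _load_sheet_tables(cfg: dict) -> dict:
    tables = {}
    for path, meta, fmt in read_sample_sheet(cfg["sample_sheet"]):
        reader = {"airr": read_airr, "mixcr": read_mixcr_tsv}.get(fmt)
        if reader is None:
            raise ConfigError(f"unsupported sample-sheet format {fmt!r}")
        tables[meta.sample_id] = reader(path, meta)
    return tables


def run_pipeline(cfg: dict, outdir, seed: int | None = None) -> pd.DataFrame:
    """Execute a validated run configuration; returns the manifest.

    ``seed`` overrides ``cfg['seed']``. With a ``simulation`` input the
    full synthetic experiment is generated and every analysis stage runs
    on the allo and poly arms; with a ``sample_sheet`` input the listed
    tables are analyzed as one group.
    """
    cfg = validate_config(cfg)
    if seed is not None:
        cfg["seed"] = int(seed)
    seed = int(cfg.get("seed", 0))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    stages = cfg["stages"]

    if "simulation" in cfg:
        sim_cfg = SimulationConfig(**{**(cfg["simulation"] or {}), "seed": seed})
        exp = simulate_experiment(sim_cfg)
        tables = {exp.donor.meta.sample_id: exp.donor}
        grafts = {}
        organ_sets = {}  # (mode) -> {organ: pooled table}
        for mode in ("poly", "allo"):
            grafts[mode] = exp.products[mode]
            tables[exp.products[mode].meta.sample_id] = exp.products[mode]
            for key, t in exp.seeded[mode].items():
                tables[t.meta.sample_id] = t
            organ_sets[mode] = {
                organ: pool_samples(
                    [exp.seeded[mode][(f"r{r + 1}", organ)]
                     for r in range(sim_cfg.n_recipients)],
                    label=f"{mode}_pooled_{organ}",
                )
                for organ in ORGANS
            }
        for sid, t in tables.items():
            path = outdir / f"{sid}.airr.tsv"
            write_clonotype_table(t, path)
            _emit(manifest, "simulate", path)
        truth_path = outdir / "ground_truth.tsv"
        pd.concat(
            [t.clones.assign(stage=t.stage) for t in exp.seeded_truths.values()]
        ).to_csv(truth_path, sep="\t", index=False)
        _emit(manifest, "simulate", truth_path)
    else:
        tables = _load_sheet_tables(cfg)
        grafts = {}
        organ_sets = {"all": {t.meta.organ: t for t in tables.values()
                              if t.meta.organ in ORGANS}}
        if cfg.get("graft_sample"):
            grafts["all"] = tables[cfg["graft_sample"]]

    table_list = list(tables.values())

    if stages["diversity"]["enabled"]:
        prof = diversity.diversity_profile(
            table_list, n_reps=stages["diversity"]["n_reps"], seed=seed
        )
        path = outdir / "diversity.tsv"
        prof.to_csv(path, sep="\t", index=False)
        _emit(manifest, "diversity", path)

    if stages["overlap"]["enabled"] and len(table_list) >= 2:
        mat = overlap.pairwise_overlap(table_list, method=stages["overlap"]["method"])
        path = outdir / f"overlap_{mat.method}.tsv"
        mat.values.to_csv(path, sep="\t")
        _emit(manifest, "overlap", path)
        links = overlap.circos_links(table_list)
        path = outdir / "overlap_links.tsv"
        links.to_csv(path, sep="\t", index=False)
        _emit(manifest, "overlap", path)

    if stages["barycentric"]["enabled"]:
        for mode, organs in organ_sets.items():
            if len(organs) != 3:
                continue
            tri = barycentric.barycentric_table(
                [organs[o] for o in ORGANS],
                normalization=stages["barycentric"]["normalization"],
                dominance_threshold=stages["barycentric"]["dominance_threshold"],
            )
            path = outdir / f"barycentric_{mode}.tsv"
            tri.to_csv(path, sep="\t", index=False)
            _emit(manifest, "barycentric", path)

    if stages["tsea"]["enabled"]:
        rows = []
        for mode, graft in grafts.items():
            ref = tsea.rank_reference(graft)
            for organ, table in organ_sets.get(mode, {}).items():
                query = set(counts_by_key(table).index)
                res = tsea.tsea_test(
                    query, ref, n_perm=stages["tsea"]["n_perm"], seed=seed,
                    alternative=stages["tsea"]["alternative"],
                )
                rows.append(
                    {
                        "graft": graft.meta.sample_id,
                        "organ": organ,
                        "query_size": res.query_size,
                        "hits": res.hits,
                        "missing": res.missing,
                        "mean_rank_stat": res.mean_rank_stat,
                        "es": res.es,
                        "p_value": res.p_value,
                        "n_perm": res.n_perm,
                    }
                )
        if rows:
            path = outdir / "tsea.tsv"
            pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
            _emit(manifest, "tsea", path)

    if stages["usage"]["enabled"]:
        usage = segment_usage.usage_matrix(
            table_list, weighting=stages["usage"]["weighting"]
        )
        path = outdir / "segment_usage.tsv"
        usage.to_csv(path, sep="\t")
        _emit(manifest, "usage", path)
        for mode, organs in organ_sets.items():
            if len(organs) < 2:
                continue
            enr = segment_usage.segment_set_enrichment(
                organs, segment_set=stages["usage"]["segment_set"]
            )
            path = outdir / f"segment_enrichment_{mode}.tsv"
            enr.to_csv(path, sep="\t", index=False)
            _emit(manifest, "usage", path)

    mf = pd.DataFrame(manifest, columns=["stage", "path", "sha256"])
    mf_path = outdir / "manifest.tsv"
    mf.to_csv(mf_path, sep="\t", index=False)
    with open(outdir / "run_config.yaml", "w") as fh:
        yaml.safe_dump({k: v for k, v in cfg.items()}, fh, sort_keys=True)
    return mf
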
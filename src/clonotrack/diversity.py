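"""Rarefaction and inverse-Simpson diversity of clonotype tables.

The inverse Simpson index (iSI) ``1 / sum(p_i^2)`` is the effective
number of equally sized clones: it equals the richness K for a uniform
K-clone repertoire and 1 for a monoclonal one. Because iSI is sensitive
to sequencing depth, samples are compared after rarefying every table to
a common UMI depth by sampling without replacement (each UMI is one
distinct mRNA molecule, so the draw is multivariate hypergeometric).
"""

from __future__ import annotations

import zlib
from dataclasses import replace

import numpy as np
import pandas as pd

from .errors import DepthError, EmptyTableError, UndefinedStatisticError
from .io import RepertoireTable


def sample_seed(global_seed: int, sample_id: str) -> int:
    """Per-sample seed: global seed offset by a stable hash of the sample
    id, so adding samples never reshuffles existing results."""
    return (int(global_seed) + zlib.crc32(sample_id.encode("utf-8"))) % (2**31)


def downsample(table: RepertoireTable, depth: int, seed: int) -> RepertoireTable:
    """Rarefy a table to ``depth`` UMIs without replacement.

    Deterministic given ``seed``. Raises :class:`DepthError` if ``depth``
    exceeds the table's total (no upsampling).
    """
    depth = int(depth)
    if depth < 0:
        raise DepthError(f"negative depth {depth}")
    total = table.total_umis
    if depth > total:
        raise DepthError(
            f"depth {depth} exceeds total_umis {total} of {table.meta.sample_id}"
        )
    rng = np.random.default_rng(seed)
    counts = table.records["umi_count"].to_numpy()
    new_counts = rng.multivariate_hypergeometric(counts, depth)
    kept = new_counts > 0
    records = table.records.loc[kept].assign(umi_count=new_counts[kept])
    return RepertoireTable(meta=replace(table.meta), records=records.reset_index(drop=True))


def inverse_simpson(table_or_counts) -> float:
    """Inverse Simpson index ``1 / sum(p_i^2)`` of a repertoire.

    Accepts a :class:`RepertoireTable` or any array of clone counts.
    Scale-invariant in the counts; undefined for an empty repertoire.
    """
    if isinstance(table_or_counts, RepertoireTable):
        counts = table_or_counts.records["umi_count"].to_numpy(dtype=float)
    else:
        counts = np.asarray(table_or_counts, dtype=float)
        counts = counts[counts > 0]
    total = counts.sum()
    if counts.size == 0 or total <= 0:
        raise UndefinedStatisticError("inverse Simpson undefined for empty repertoire")
    p = counts / total
    return float(1.0 / np.sum(p * p))


def diversity_profile(
    tables: list[RepertoireTable],
    depth_policy: str = "min_common",
    depth: int | None = None,
    n_reps: int = 25,
    seed: int = 0,
) -> pd.DataFrame:
    """Downsampled iSI for a group of samples at a common depth.

    ``depth_policy='min_common'`` rarefies everything to the smallest
    total among the tables; ``'fixed'`` uses ``depth``. For each table
    the reported iSI is the mean over ``n_reps`` independent downsamples
    (SD reported alongside), each stream seeded per sample.

    Returns a DataFrame with columns ``sample_id, depth, n_reps, isi,
    isi_sd, seed``.
    """
    if not tables:
        raise EmptyTableError("diversity_profile needs at least one table")
    for t in tables:
        if t.n_clonotypes == 0:
            raise EmptyTableError(f"empty table {t.meta.sample_id}")
    if depth_policy == "min_common":
        common = min(t.total_umis for t in tables)
    elif depth_policy == "fixed":
        if depth is None:
            raise DepthError("fixed depth policy requires depth")
        common = int(depth)
        for t in tables:
            if common > t.total_umis:
                raise DepthError(
                    f"fixed depth {common} exceeds total of sample {t.meta.sample_id}"
                )
    else:
        raise DepthError(f"unknown depth policy {depth_policy!r}")

    out = []
    for t in tables:
        s = sample_seed(seed, t.meta.sample_id)
        rep_seeds = np.random.SeedSequence(s).generate_state(n_reps) % (2**31)
        values = [inverse_simpson(downsample(t, common, rs)) for rs in rep_seeds]
        out.append(
            {
                "sample_id": t.meta.sample_id,
                "depth": common,
                "n_reps": n_reps,
                "isi": float(np.mean(values)),
                "isi_sd": float(np.std(values, ddof=1)) if n_reps > 1 else 0.0,
                "seed": s,
            }
        )
    return pd.DataFrame(out)
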
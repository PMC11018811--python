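"""Barycentric clone-distribution geometry over three compartments.

Every clonotype detected in up to three compartments (e.g. spleen,
liver, colon, or three replicates of one organ) is mapped to a point in
a triangle: the weight on each vertex is the compartment's share of the
clone, and a normalized size makes bubbles comparable across clones.
Clones sitting on a vertex are organ-restricted; clones near the
centroid span all compartments.

Default normalization works on per-compartment frequencies (counts over
compartment depth) before computing weights, because sequencing depths
of different organs differ by orders of magnitude; ``raw`` mode uses
counts directly and suits replicate-to-replicate triangles of comparable
depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, UndefinedStatisticError
from .io import RepertoireTable, counts_by_key

_SQRT3_2 = np.sqrt(3.0) / 2.0


@dataclass(frozen=True)
class BarycentricPoint:
    """A clone's position in the compartment triangle.

    ``weights`` sum to 1; a zero weight means the clone is undetected in
    that compartment. ``size`` is the normalized clone size (mean
    per-compartment frequency in frequency mode).
    """

    clone_key: str | None
    weights: tuple[float, float, float]
    size: float
    raw_counts: tuple[int, int, int]


def barycentric_coordinates(
    counts, depths, normalization: str = "frequency", clone_key: str | None = None
) -> BarycentricPoint:
    """Map per-compartment counts of one clone to triangle weights.

    frequency mode: ``f_X = count_X / depth_X``, ``w_X = f_X / sum(f)``
    and size = mean of the f's. raw mode: ``w_X = count_X / sum(counts)``
    and size = ``sum(counts) / sum(depths)``.
    """
    counts = np.asarray(counts, dtype=float)
    depths = np.asarray(depths, dtype=float)
    if counts.shape != (3,) or depths.shape != (3,):
        raise ConfigError("barycentric coordinates require exactly 3 compartments")
    if (counts < 0).any():
        raise ConfigError("negative counts")
    if counts.sum() == 0:
        raise UndefinedStatisticError("all-zero counts: barycentric point undefined")
    if ((counts > 0) & (depths <= 0)).any():
        raise ConfigError("positive count in a compartment with zero depth")

    if normalization == "frequency":
        f = np.divide(counts, depths, out=np.zeros(3), where=depths > 0)
        w = f / f.sum()
        size = float(f.sum() / 3.0)  # mean per-compartment frequency
    elif normalization == "raw":
        w = counts / counts.sum()
        size = float(counts.sum() / depths.sum())
    else:
        raise ConfigError(f"unknown normalization {normalization!r}")
    return BarycentricPoint(
        clone_key=clone_key,
        weights=tuple(float(v) for v in w),
        size=size,
        raw_counts=tuple(int(v) for v in counts),
    )


def classify_distribution(point: BarycentricPoint,
                          dominance_threshold: float = 0.9) -> str:
    """Label a clone ``restricted(X)`` (all weight on one compartment),
    ``biased(X)`` (weight >= threshold on one compartment) or
    ``ubiquitous``. The threshold must exceed 1/3 to be meaningful."""
    if not (1.0 / 3.0 < dominance_threshold <= 1.0):
        raise ConfigError("dominance_threshold must lie in (1/3, 1]")
    w = np.asarray(point.weights)
    labels = "ABC"
    top = int(np.argmax(w))
    if w[top] == 1.0:
        return f"restricted({labels[top]})"
    if w[top] >= dominance_threshold:
        return f"biased({labels[top]})"
    return "ubiquitous"


def barycentric_table(
    tables: list[RepertoireTable],
    normalization: str = "frequency",
    dominance_threshold: float = 0.9,
    level: str = "nt",
) -> pd.DataFrame:
    """Barycentric points for every clone detected in any of three
    compartments.

    Returns a DataFrame with columns ``clone_key, w_a, w_b, w_c, size,
    class`` plus triangle-plot coordinates ``x = w_b + w_c/2``,
    ``y = sqrt(3)/2 * w_c``; compartment order follows the input order.
    """
    if len(tables) != 3:
        raise ConfigError("barycentric_table requires exactly 3 compartments")
    counts = pd.concat(
        [counts_by_key(t, level=level).rename(i) for i, t in enumerate(tables)], axis=1
    ).fillna(0)
    depths = np.array([t.total_umis for t in tables], dtype=float)

    c = counts.to_numpy(dtype=float)
    if normalization == "frequency":
        f = c / depths
        w = f / f.sum(axis=1, keepdims=True)
        size = f.sum(axis=1) / 3.0
    elif normalization == "raw":
        w = c / c.sum(axis=1, keepdims=True)
        size = c.sum(axis=1) / depths.sum()
    else:
        raise ConfigError(f"unknown normalization {normalization!r}")

    out = pd.DataFrame(
        {
            "clone_key": counts.index,
            "w_a": w[:, 0],
            "w_b": w[:, 1],
            "w_c": w[:, 2],
            "size": size,
        }
    )
    out["x"] = out["w_b"] + out["w_c"] / 2.0
    out["y"] = _SQRT3_2 * out["w_c"]
    points = [
        BarycentricPoint(None, (wa, wb, wc), s, (0, 0, 0))
        for wa, wb, wc, s in zip(out["w_a"], out["w_b"], out["w_c"], out["size"])
    ]
    out["class"] = [classify_distribution(p, dominance_threshold) for p in points]
    return out.reset_index(drop=True)


def top_clones(obj, n: int):
    """The ``n`` largest clones, ties broken by lexicographic clone key.

    Accepts a :class:`RepertoireTable` (size = UMI count) or a DataFrame
    from :func:`barycentric_table` (size column). Asking for more clones
    than exist returns everything with a warning.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    if isinstance(obj, RepertoireTable):
        sizes = counts_by_key(obj)
        ranked = sizes.sort_index().sort_values(ascending=False, kind="stable")
        if n > len(ranked):
            warnings.warn(f"requested {n} clones but only {len(ranked)} exist",
                          stacklevel=2)
            n = len(ranked)
        return ranked.iloc[:n]
    df = obj.sort_values("clone_key").sort_values("size", ascending=False,
                                                  kind="stable")
    if n > len(df):
        warnings.warn(f"requested {n} clones but only {len(df)} exist", stacklevel=2)
        n = len(df)
    return df.iloc[:n].reset_index(drop=True)
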
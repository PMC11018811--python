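"""Pairwise repertoire similarity and UMI-overlap sharing summaries.

Two abundance-weighted indices are provided. Morisita-Horn,
``2*sum(p*q) / (sum(p^2) + sum(q^2))`` over the union of clonotype keys,
is bounded in [0, 1] and defined for proportions; it is the default.
Classical Morisita replaces the squared-proportion terms with unbiased
Simpson estimates ``sum(n*(n-1)) / (N*(N-1))`` and may slightly exceed 1
for small samples. Directional UMI-overlap fractions (share of a
sample's molecules whose clonotype is also seen in the partner) feed
circos-style sharing plots.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError
from .io import PairedCloneTable, RepertoireTable, counts_by_key, paired_counts_by_key


def _key_counts(obj, level: str = "nt") -> pd.Series:
    if isinstance(obj, RepertoireTable):
        return counts_by_key(obj, level=level)
    if isinstance(obj, PairedCloneTable):
        return paired_counts_by_key(obj)
    return pd.Series(obj, dtype=float)


def _aligned(x, y, level: str = "nt"):
    cx, cy = _key_counts(x, level), _key_counts(y, level)
    union = cx.index.union(cy.index)
    return (
        cx.reindex(union, fill_value=0).to_numpy(dtype=float),
        cy.reindex(union, fill_value=0).to_numpy(dtype=float),
    )


def morisita_horn(x, y, level: str = "nt") -> float:
    """Morisita-Horn similarity in [0, 1]; 1 iff identical proportion
    vectors, 0 iff disjoint clonotype sets."""
    a, b = _aligned(x, y, level)
    if a.sum() == 0 or b.sum() == 0:
        raise UndefinedStatisticError("Morisita-Horn undefined for empty repertoire")
    p, q = a / a.sum(), b / b.sum()
    denom = np.sum(p * p) + np.sum(q * q)
    return float(2.0 * np.sum(p * q) / denom)


def morisita_classical(x, y, level: str = "nt") -> float:
    """Classical Morisita index with unbiased Simpson terms.

    ``C = 2*sum(x_i*y_i) / ((lam_x + lam_y) * X * Y)`` with
    ``lam = sum(n*(n-1)) / (N*(N-1))``. Requires integer counts with at
    least 2 molecules per table; values slightly above 1 can occur for
    small samples and trigger a warning.
    """
    a, b = _aligned(x, y, level)
    X, Y = a.sum(), b.sum()
    if X < 2 or Y < 2:
        raise UndefinedStatisticError("classical Morisita needs totals >= 2")
    lam_x = np.sum(a * (a - 1)) / (X * (X - 1))
    lam_y = np.sum(b * (b - 1)) / (Y * (Y - 1))
    if lam_x + lam_y == 0:
        # both samples are all-singletons; no within-sample recapture signal
        raise UndefinedStatisticError("classical Morisita undefined: both "
                                      "repertoires consist of singletons")
    value = float(2.0 * np.sum(a * b) / ((lam_x + lam_y) * X * Y))
    if value > 1.0:
        warnings.warn(
            f"classical Morisita {value:.4f} > 1 (small-sample bias)",
            stacklevel=2,
        )
    return value


def umi_overlap_fraction(x, y, mode: str = "directional", level: str = "nt") -> float:
    """Fraction of UMIs on shared clonotypes.

    ``directional``: share of x's molecules whose clonotype key also
    appears in y. ``pooled``: shared-clonotype molecules of both samples
    over the combined total.
    """
    a, b = _aligned(x, y, level)
    shared = (a > 0) & (b > 0)
    if mode == "directional":
        if a.sum() == 0:
            raise UndefinedStatisticError("overlap fraction undefined for empty x")
        return float(a[shared].sum() / a.sum())
    if mode == "pooled":
        total = a.sum() + b.sum()
        if total == 0:
            raise UndefinedStatisticError("overlap fraction undefined: both empty")
        return float((a[shared].sum() + b[shared].sum()) / total)
    raise UndefinedStatisticError(f"unknown overlap mode {mode!r}")


@dataclass
class OverlapMatrix:
    """Square similarity/overlap matrix over samples.

    ``values`` is a DataFrame indexed and columned by sample id. For
    ``umi_fraction`` the matrix is directional (row -> column) and need
    not be symmetric.
    """

    sample_ids: list[str]
    method: str
    values: pd.DataFrame


def _table_id(obj, i: int) -> str:
    if isinstance(obj, RepertoireTable):
        return obj.meta.sample_id
    if isinstance(obj, PairedCloneTable):
        return obj.sample_id
    return f"sample_{i}"


def pairwise_overlap(tables: list, method: str = "morisita_horn",
                     level: str = "nt") -> OverlapMatrix:
    """All-pairs overlap matrix.

    ``method`` is ``morisita_horn`` (symmetric, unit diagonal),
    ``morisita_classical`` or ``umi_fraction`` (directional). Pairs for
    which the statistic is undefined are reported as NaN.
    """
    if len(tables) < 2:
        raise UndefinedStatisticError("pairwise_overlap needs >= 2 tables")
    ids = [_table_id(t, i) for i, t in enumerate(tables)]
    n = len(tables)
    values = np.full((n, n), np.nan)
    funcs = {
        "morisita_horn": morisita_horn,
        "morisita_classical": morisita_classical,
        "umi_fraction": lambda x, y, level: umi_overlap_fraction(x, y, "directional", level),
    }
    if method not in funcs:
        raise UndefinedStatisticError(f"unknown overlap method {method!r}")
    fn = funcs[method]
    for i in range(n):
        for j in range(n):
            if j < i and method != "umi_fraction":
                values[i, j] = values[j, i]
                continue
            try:
                values[i, j] = fn(tables[i], tables[j], level)
            except UndefinedStatisticError:
                values[i, j] = np.nan
    return OverlapMatrix(
        sample_ids=ids,
        method=method,
        values=pd.DataFrame(values, index=ids, columns=ids),
    )


def sharing_summary(tables: list, level: str = "nt") -> pd.DataFrame:
    """Clonotype detection-pattern counts across samples.

    For every subset pattern of samples in which a clonotype is detected,
    reports the number of clonotypes with exactly that pattern and the
    total UMI/cell mass they carry. Pattern labels join sample ids with
    '+'; masses sum to the union totals over all samples.
    """
    if len(tables) < 2:
        raise UndefinedStatisticError("sharing_summary needs >= 2 tables")
    ids = [_table_id(t, i) for i, t in enumerate(tables)]
    counts = pd.concat(
        [_key_counts(t, level).rename(sid) for sid, t in zip(ids, tables)],
        axis=1,
    ).fillna(0)
    present = counts > 0
    pattern = present.apply(lambda row: "+".join(c for c in ids if row[c]), axis=1)
    grouped = counts.groupby(pattern)
    out = pd.DataFrame(
        {
            "n_clonotypes": grouped.size(),
            "total_mass": grouped.sum().sum(axis=1),
        }
    )
    out.index.name = "pattern"
    return out.reset_index()


def circos_links(tables: list, level: str = "nt") -> pd.DataFrame:
    """Circos-ready link table of pairwise sharing.

    One row per unordered sample pair: the shared clonotype mass in each
    endpoint as a fraction of that endpoint's total (directional), plus
    the absolute shared mass.
    """
    ids = [_table_id(t, i) for i, t in enumerate(tables)]
    rows = []
    for (i, x), (j, y) in itertools.combinations(enumerate(tables), 2):
        a, b = _aligned(x, y, level)
        shared = (a > 0) & (b > 0)
        rows.append(
            {
                "source": ids[i],
                "target": ids[j],
                "source_fraction": a[shared].sum() / a.sum() if a.sum() else np.nan,
                "target_fraction": b[shared].sum() / b.sum() if b.sum() else np.nan,
                "shared_mass": a[shared].sum() + b[shared].sum(),
            }
        )
    return pd.DataFrame(rows)
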
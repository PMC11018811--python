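"""V-beta (Trbv) gene-segment usage and set enrichment.

Per-sample segment frequencies can be weighted by clone (each clonotype
counts once) or by UMI/cell mass. Records with ambiguous multi-hit V
calls are excluded by default (and counted), matching the convention of
segment-level usage summaries; ``keep_first`` retains them under their
best hit.

Enrichment of a designated segment set (default: the colon-enriched
TRBV12-1 / TRBV12-2 / TRBV26 trio) across groups uses a two-sided
Fisher exact test per group against all other groups pooled, with
Benjamini-Hochberg correction across groups. The two-sided p is the
standard convention: the sum of probabilities of all fixed-margin
tables no more probable than the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, EmptyTableError, UndefinedStatisticError
from .io import (
    PairedCloneTable,
    RepertoireTable,
    is_ambiguous_call,
    primary_segment,
)

#: the colon-enriched V-beta trio
DEFAULT_SEGMENT_SET = frozenset({"TRBV12-1", "TRBV12-2", "TRBV26"})


def normalize_segment(name: str) -> str:
    """Case-insensitive, separator-normalized segment name
    ('Trbv12.1' == 'TRBV12-1')."""
    return str(name).strip().upper().replace(".", "-")


@dataclass
class SegmentUsage:
    sample_id: str
    frequencies: pd.Series  # segment name -> proportion, sums to 1
    weighting: str
    excluded_ambiguous: int


def segment_frequencies(
    table: RepertoireTable,
    weighting: str = "by_clone",
    ambig_policy: str = "exclude",
) -> SegmentUsage:
    """Per-segment usage proportions for one sample."""
    if weighting not in ("by_clone", "by_umi"):
        raise ConfigError(f"unknown weighting {weighting!r}")
    if ambig_policy not in ("exclude", "keep_first"):
        raise ConfigError(f"unknown ambiguity policy {ambig_policy!r}")
    r = table.records
    if r.empty:
        raise EmptyTableError("segment usage of an empty table")
    ambig = r["v_call"].map(is_ambiguous_call)
    excluded = 0
    if ambig_policy == "exclude":
        excluded = int(ambig.sum())
        r = r[~ambig]
        if r.empty:
            raise EmptyTableError("all records carry ambiguous V calls")
    seg = r["v_call"].map(primary_segment).map(normalize_segment)
    weights = r["umi_count"] if weighting == "by_umi" else pd.Series(1, index=r.index)
    counts = weights.groupby(seg).sum().sort_index()
    return SegmentUsage(
        sample_id=table.meta.sample_id,
        frequencies=counts / counts.sum(),
        weighting=weighting,
        excluded_ambiguous=excluded,
    )


def usage_matrix(tables: list[RepertoireTable], weighting: str = "by_clone",
                 ambig_policy: str = "exclude") -> pd.DataFrame:
    """Samples x segments frequency matrix (rows sum to 1)."""
    rows = {}
    for t in tables:
        rows[t.meta.sample_id] = segment_frequencies(t, weighting, ambig_policy).frequencies
    return pd.DataFrame(rows).T.fillna(0.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order kept."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ConfigError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _segment_counts(obj, unit: str, ambig_policy: str) -> pd.Series:
    """Counts of analysis units (clones or UMIs/cells) per beta segment."""
    if isinstance(obj, RepertoireTable):
        r = obj.records
        ambig = r["v_call"].map(is_ambiguous_call)
        if ambig_policy == "exclude":
            r = r[~ambig]
        seg = r["v_call"].map(primary_segment).map(normalize_segment)
        w = r["umi_count"] if unit == "cell" else pd.Series(1, index=r.index)
        return w.groupby(seg).sum()
    if isinstance(obj, PairedCloneTable):
        c = obj.clones
        seg = c["trb_v"].map(primary_segment).map(normalize_segment)
        w = c["cell_count"] if unit == "cell" else pd.Series(1, index=c.index)
        return w.groupby(seg).sum()
    # plain mapping segment -> count
    s = pd.Series(obj, dtype=float)
    s.index = s.index.map(normalize_segment)
    return s.groupby(level=0).sum()


def segment_set_enrichment(
    groups: dict,
    segment_set=DEFAULT_SEGMENT_SET,
    unit: str = "clone",
    ambig_policy: str = "exclude",
) -> pd.DataFrame:
    """Fisher/BH enrichment of a segment set per group vs all others.

    ``groups`` maps a group label (organ, cluster...) to a
    RepertoireTable, a PairedCloneTable, or a precomputed
    segment -> count mapping. For each group a 2x2 table
    (in-set vs out-of-set) x (this group vs rest) is tested with a
    two-sided Fisher exact test; the sample odds ratio uses a Haldane
    0.5 continuity correction when a cell is zero (flagged). p-values
    are BH-adjusted across groups.
    """
    if len(groups) < 2:
        raise ConfigError("segment_set_enrichment needs >= 2 groups")
    segment_set = {normalize_segment(s) for s in segment_set}
    per_group = {}
    for label, obj in groups.items():
        counts = _segment_counts(obj, unit, ambig_policy)
        if counts.sum() == 0:
            continue
        in_set = counts[counts.index.isin(segment_set)].sum()
        per_group[label] = (float(in_set), float(counts.sum() - in_set))
    if len(per_group) < 2:
        raise UndefinedStatisticError("fewer than 2 non-empty groups")

    tot_in = sum(v[0] for v in per_group.values())
    tot_out = sum(v[1] for v in per_group.values())
    rows = []
    for label, (a, b) in per_group.items():
        c, d = tot_in - a, tot_out - b
        table = np.array([[a, b], [c, d]])
        _, p = stats.fisher_exact(np.round(table).astype(int), alternative="two-sided")
        haldane = bool((table == 0).any())
        if haldane:
            table = table + 0.5
        odds = (table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0])
        rows.append(
            {
                "group": label,
                "set_count_in": a,
                "other_count_in": b,
                "set_count_out": c,
                "other_count_out": d,
                "odds_ratio": float(odds),
                "haldane_corrected": haldane,
                "p": float(p),
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p by explicit fixed-margin enumeration.

    Sums hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed the observed one. Kept as
    an independent, enumeration-based route (scipy is used in the main
    enrichment path).
    """
    (a, b), (c, d) = np.asarray(table, dtype=int)
    r1, n = a + b, a + b + c + d
    c1 = a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    p_obs = stats.hypergeom.pmf(a, n, c1, r1)
    return float(pmf[pmf <= p_obs * (1 + 1e-10)].sum())
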
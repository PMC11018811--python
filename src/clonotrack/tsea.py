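"""TCR set enrichment analysis (TSEA).

Tests whether a set of clonotypes (e.g. those re-detected in a host
organ) concentrates among the high-frequency ranks of a reference
repertoire (the grafted cell product). The primary statistic is the
standardized mean rank of the hits: drawing k ranks without replacement
from 1..N has mean (N+1)/2 and variance of the mean
(N+1)(N-k)/(12k), so

    z = (E0 - mean_rank) / SD0

is positive when hits sit above (i.e. at better ranks than) chance.
Significance comes from a permutation null over random same-size key
sets, with the add-one estimator p = (1 + #{perm >= obs}) / (n_perm + 1)
so p can never be zero. A GSEA-style running-sum enrichment score and a
windowed "worm" density (relative hit enrichment along the ranking, on
a fixed scale with 1 = neutral) are reported for visual parity with
barcode-plot displays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, EmptyTableError, NoHitsError
from .io import RepertoireTable, counts_by_key


@dataclass
class RankedReference:
    """Reference clonotypes ordered by descending frequency.

    ``keys[0]`` has rank 1 (most frequent); frequencies sum to 1 and are
    non-increasing. Ties are broken lexicographically by key so the
    ranking is deterministic.
    """

    keys: np.ndarray
    frequencies: np.ndarray
    tie_policy: str = "descending count, ties by lexicographic key"

    def __post_init__(self) -> None:
        self.keys = np.asarray(self.keys, dtype=object)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if np.any(np.diff(self.frequencies) > 1e-12):
            raise ConfigError("reference frequencies must be non-increasing")

    def __len__(self) -> int:
        return len(self.keys)

    @property
    def rank_of(self) -> dict:
        if not hasattr(self, "_rank_of"):
            self._rank_of = {k: i + 1 for i, k in enumerate(self.keys)}
        return self._rank_of


@dataclass
class TseaResult:
    query_size: int
    hits: int
    missing: int  # query keys absent from the reference (carry no rank)
    hit_ranks: np.ndarray
    mean_rank_stat: float
    es: float
    p_value: float
    n_perm: int
    alternative: str
    worm: np.ndarray
    window: int
    step: int
    seed: int
    worm_scale: dict = field(default_factory=dict)


def rank_reference(graft: RepertoireTable, level: str = "nt") -> RankedReference:
    """Frequency-rank a graft repertoire into a :class:`RankedReference`."""
    counts = counts_by_key(graft, level=level)
    if counts.empty:
        raise EmptyTableError("cannot rank an empty graft repertoire")
    ordered = counts.sort_index().sort_values(ascending=False, kind="stable")
    freqs = ordered.to_numpy(dtype=float) / ordered.sum()
    return RankedReference(keys=ordered.index.to_numpy(dtype=object), frequencies=freqs)


def _mean_rank_null_moments(n: int, k: int) -> tuple[float, float]:
    """Mean and SD of the mean of k ranks drawn without replacement from
    1..N (finite-population closed forms)."""
    e0 = (n + 1) / 2.0
    var = (n + 1) * (n - k) / (12.0 * k)
    return e0, np.sqrt(var)


def running_sum_es(hit_ranks: np.ndarray, n: int) -> float:
    """GSEA-style enrichment score: maximal deviation of the running sum
    that gains 1/k at each hit rank and loses 1/(N-k) at each miss."""
    k = len(hit_ranks)
    if k == 0 or k == n:
        return 0.0
    is_hit = np.zeros(n, dtype=bool)
    is_hit[np.asarray(hit_ranks, dtype=int) - 1] = True
    steps = np.where(is_hit, 1.0 / k, -1.0 / (n - k))
    rs = np.cumsum(steps)
    return float(rs[np.argmax(np.abs(rs))])


def tsea_test(
    query,
    ref: RankedReference,
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "toward_top",
    window: int | None = None,
    step: int | None = None,
) -> TseaResult:
    """Permutation test for frequency-rank enrichment of a clonotype set.

    ``query`` is a set of clonotype keys; keys absent from the reference
    are reported as ``missing`` and excluded from ranks. The null draws
    random key sets of the same size (ranks without replacement).
    ``alternative='toward_top'`` rejects for concentration at high
    frequencies; ``'two_sided'`` for either tail.
    """
    if n_perm < 99:
        raise ConfigError("n_perm must be >= 99")
    query = set(query)
    if not query:
        raise ConfigError("empty query set")
    n = len(ref)
    ranks = np.array(sorted(ref.rank_of[k] for k in query if k in ref.rank_of))
    k = len(ranks)
    if k == 0:
        raise NoHitsError("query shares no clonotype with the reference")

    e0, sd0 = _mean_rank_null_moments(n, k)
    if sd0 == 0:  # saturated query: every reference key is a hit
        stat = 0.0
    else:
        stat = float((e0 - ranks.mean()) / sd0)

    rng = np.random.default_rng(seed)
    all_ranks = np.arange(1, n + 1)
    perm_means = np.empty(n_perm)
    for i in range(n_perm):
        perm_means[i] = rng.choice(all_ranks, size=k, replace=False).mean()
    if sd0 == 0:
        perm_stats = np.zeros(n_perm)
    else:
        perm_stats = (e0 - perm_means) / sd0
    if alternative == "toward_top":
        exceed = perm_stats >= stat
    elif alternative == "two_sided":
        exceed = np.abs(perm_stats) >= abs(stat)
    else:
        raise ConfigError(f"unknown alternative {alternative!r}")
    p = (1.0 + int(exceed.sum())) / (n_perm + 1.0)

    if window is None:
        window = max(1, int(np.ceil(n / 20)))
    if step is None:
        step = window
    worm = worm_density(query, ref, window=window, step=step)
    return TseaResult(
        query_size=len(query),
        hits=k,
        missing=len(query) - k,
        hit_ranks=ranks,
        mean_rank_stat=stat,
        es=running_sum_es(ranks, n),
        p_value=float(p),
        n_perm=n_perm,
        alternative=alternative,
        worm=worm,
        window=window,
        step=step,
        seed=seed,
        worm_scale={"neutral": 1.0, "max": n / window},
    )


def worm_density(query, ref: RankedReference, window: int, step: int | None = None
                 ) -> np.ndarray:
    """Windowed relative enrichment density along the ranking.

    For each window position the density is
    ``(hits in window / window) / (k / N)``: 1 is neutral, 0 means no
    hits, N/window is the ceiling. The scale is fixed by (window, N)
    alone, so worms from different queries over the same reference are
    directly comparable.
    """
    n = len(ref)
    if not (1 <= window <= n):
        raise ConfigError(f"window {window} outside 1..{n}")
    if step is None:
        step = window
    if step < 1:
        raise ConfigError("step must be >= 1")
    query = set(query)
    ranks = np.array(sorted(ref.rank_of[k] for k in query if k in ref.rank_of))
    starts = np.arange(0, n, step)  # one entry per ceil(N/step) positions
    out = np.zeros(len(starts))
    k = len(ranks)
    if k == 0:
        warnings.warn("empty query: worm density is all-zero", stacklevel=2)
        return out
    base = k / n
    for i, s in enumerate(starts):
        in_win = np.sum((ranks > s) & (ranks <= s + window))
        out[i] = (in_win / window) / base
    return out
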
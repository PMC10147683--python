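"""Enrichment and association statistics.

The centrepiece is the exact multi-set intersection test: the null
distribution of the size of an m-way intersection when each set is an
independent uniform random subset of fixed size drawn from a universe of N
elements.  For m = 2 this is the hypergeometric distribution; for m > 2 the
exact law is obtained by conditioning on the running intersection size —
given |A1 ∩ ... ∩ Ak| = i, that intersection is itself a uniform random
i-subset, so intersecting with the next set is again hypergeometric.  The
tail is accumulated in log space so p-values far below float underflow
(e.g. 1e-260) remain meaningful.

Also here: the observed/expected chi-square on a 2x2 table (no continuity
correction), hypergeometric over-representation, preranked GSEA with the
weighted running-sum statistic, Spearman correlation, and Benjamini-Hochberg
adjustment.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import logsumexp

__all__ = [
    "MultiSetTestResult",
    "ObservedExpectedResult",
    "GseaResult",
    "multiset_intersection_test",
    "observed_expected_chi2",
    "ora_test",
    "ora_collection",
    "gsea_preranked",
    "spearman",
    "bh_adjust",
]


# ---------------------------------------------------------------------------
# exact multi-set intersection test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MultiSetTestResult:
    m: int
    universe_size: int
    set_sizes: tuple[int, ...]
    observed: int
    expected: float
    fold: float
    p: float
    log_p: float


def _log_intersection_pmf(n_sets: Sequence[int], N: int) -> np.ndarray:
    """log P(|A1 ∩ ... ∩ Am| = k) for k = 0..min(n_i).

    Iterated hypergeometric conditioning: start with the degenerate
    distribution at n_1, then for each further set size n, mix
    Hypergeom(N, i, n) over the current distribution of the running
    intersection size i.
    """
    sizes = list(n_sets)
    support = sizes[0]
    log_pmf = np.full(support + 1, -np.inf)
    log_pmf[support] = 0.0
    for n in sizes[1:]:
        new_support = min(support, n)
        ks = np.arange(new_support + 1)
        out = np.full(new_support + 1, -np.inf)
        for i in np.flatnonzero(np.isfinite(log_pmf)):
            # drawing n of N items, i of which are "marked"
            lp = sps.hypergeom.logpmf(ks, N, i, n)
            out = np.logaddexp(out, log_pmf[i] + lp)
        log_pmf = out
        support = new_support
    return log_pmf


def multiset_intersection_test(
    sets: Sequence[Iterable[str]], universe_size: int
) -> MultiSetTestResult:
    """Exact test for the size of an m-way set intersection.

    ``expected = N * prod(n_i / N)`` and ``p = P(X >= observed)`` under
    independent uniform subsets of the stated sizes.  Requires m >= 2 and
    every set contained in a universe of ``universe_size`` elements.
    """
    materialized = [frozenset(s) for s in sets]
    if len(materialized) < 2:
        raise ValueError("need at least two sets")
    N = int(universe_size)
    if N <= 0:
        raise ValueError("universe size must be positive")
    sizes = tuple(len(s) for s in materialized)
    if max(sizes, default=0) > N:
        raise ValueError("a set is larger than the universe")
    observed = len(frozenset.intersection(*materialized))

    expected = N * math.prod(n / N for n in sizes)
    fold = observed / expected if expected > 0 else math.inf if observed else math.nan

    if min(sizes) == 0:
        log_p = 0.0 if observed == 0 else -math.inf
    else:
        log_pmf = _log_intersection_pmf(sizes, N)
        if observed > len(log_pmf) - 1:
            log_p = -math.inf
        else:
            log_p = float(logsumexp(log_pmf[observed:]))
            log_p = min(log_p, 0.0)
    return MultiSetTestResult(
        m=len(sizes),
        universe_size=N,
        set_sizes=sizes,
        observed=observed,
        expected=expected,
        fold=fold,
        p=float(math.exp(log_p)),
        log_p=log_p,
    )


# ---------------------------------------------------------------------------
# observed/expected chi-square on a 2x2 table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ObservedExpectedResult:
    observed: np.ndarray
    expected: np.ndarray
    oe_ratio: float
    chi2: float
    p: float
    log10_p: float


def observed_expected_chi2(table: Sequence[Sequence[float]]) -> ObservedExpectedResult:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table.

    The observed/expected ratio is reported for the focal cell ``[0, 0]``
    (by convention: co-bound peaks that lost binding).  ``log10_p`` is
    computed from the log survival function so astronomically small
    p-values keep their magnitude.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {obs.shape}")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    total = obs.sum()
    if (rows <= 0).any() or (cols <= 0).any():
        raise ValueError("both margins must be positive")
    expected = np.outer(rows, cols) / total
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    # chi2(1 df) tail via the normal tail: P(X > x) = 2 P(Z > sqrt(x));
    # norm.logsf stays accurate where chi2.logsf underflows to -inf
    logsf = math.log(2.0) + float(sps.norm.logsf(math.sqrt(chi2)))
    return ObservedExpectedResult(
        observed=obs,
        expected=expected,
        oe_ratio=float(obs[0, 0] / expected[0, 0]),
        chi2=chi2,
        p=float(math.exp(logsf)),
        log10_p=logsf / math.log(10),
    )


# ---------------------------------------------------------------------------
# over-representation analysis
# ---------------------------------------------------------------------------


def ora_test(
    query: Iterable[str], gene_set: Iterable[str], universe: Iterable[str]
) -> tuple[int, float, float]:
    """Hypergeometric over-representation of ``query`` in ``gene_set``.

    Returns ``(overlap, fold, p)`` with ``p = P(X >= overlap)`` for
    X ~ Hypergeom(N=|universe|, K=|gene_set|, draws=|query|).
    """
    uni = frozenset(universe)
    if not uni:
        raise ValueError("empty universe")
    q = frozenset(query) & uni
    s = frozenset(gene_set) & uni
    if frozenset(query) - uni or frozenset(gene_set) - uni:
        raise ValueError("query and gene set must be subsets of the universe")
    N, K, n = len(uni), len(s), len(q)
    k = len(q & s)
    expected = n * K / N
    fold = k / expected if expected > 0 else math.nan
    p = float(sps.hypergeom.sf(k - 1, N, K, n)) if K and n else 1.0
    return k, fold, min(p, 1.0)


def ora_collection(
    query: Iterable[str],
    collection: Mapping[str, Iterable[str]] | "object",
    universe: Iterable[str],
) -> pd.DataFrame:
    """Run :func:`ora_test` across a collection and BH-adjust the p-values."""
    items = collection.items() if hasattr(collection, "items") else collection
    rows = []
    for name, members in items:
        k, fold, p = ora_test(query, members, universe)
        rows.append((name, len(frozenset(members)), k, fold, p))
    df = pd.DataFrame(rows, columns=["set_name", "set_size", "overlap", "fold", "p"])
    df["adj_p"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    return df


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GseaResult:
    set_name: str
    es: float
    p: float
    n_hits: int
    n_perm: int
    degenerate: bool = False


def _es_batch(hit_pos: np.ndarray, abs_scores: np.ndarray, n_total: int) -> np.ndarray:
    """Weighted running-sum enrichment scores for a batch of hit-position rows.

    ``hit_pos`` is (n_rows, k), each row sorted ascending.  Hit increments
    are proportional to |score| (weight exponent 1); misses decrement
    uniformly by 1/(N - n_hits).  The running sum starts and ends at zero
    and decreases linearly between hits, so every extreme sits immediately
    after a hit (candidate maximum) or immediately before one (candidate
    minimum): the scan is O(k) per row, independent of N.
    """
    pos = np.atleast_2d(hit_pos)
    k = pos.shape[1]
    n_miss = n_total - k
    if n_miss <= 0:
        return np.ones(pos.shape[0])
    step = 1.0 / n_miss
    w = abs_scores[pos]
    total_w = w.sum(axis=1, keepdims=True)
    safe_total = np.where(total_w > 0, total_w, 1.0)
    cum_w = np.cumsum(w, axis=1) / safe_total
    i = np.arange(1, k + 1)
    after_hit = cum_w - step * (pos + 1 - i)
    before_hit = np.concatenate(
        [np.zeros((pos.shape[0], 1)), cum_w[:, :-1]], axis=1
    ) - step * (pos - (i - 1))
    hi = after_hit.max(axis=1)
    lo = before_hit.min(axis=1)
    es = np.where(hi >= -lo, hi, lo)
    # degenerate rows where every hit has score zero: pure miss decrements
    return np.where(total_w[:, 0] > 0, es, -1.0)


def _es_from_hits(hit_pos: np.ndarray, abs_scores: np.ndarray, n_total: int) -> float:
    return float(_es_batch(hit_pos[None, :], abs_scores, n_total)[0])


def gsea_preranked(
    ranked: Mapping[str, float] | pd.Series,
    gene_set: Iterable[str],
    n_perm: int = 10_000,
    seed: int = 0,
    set_name: str = "set",
) -> GseaResult:
    """Preranked gene-set enrichment with the weighted running-sum statistic.

    Genes are ordered by decreasing score; walking down the list, members of
    ``gene_set`` add ``|score| / sum(|score| over hits)`` and non-members
    subtract ``1/(N - n_hits)``.  ES is the maximum signed deviation of this
    running sum.  The null is built by gene-label permutation (random sets
    of the same size); ``p = (1 + #{same-sign perms with |ES| >= |ES_obs|})
    / (1 + #same-sign perms)``.

    A set covering every ranked gene has no miss steps; ES is defined as +1
    and the result flagged degenerate.
    """
    if isinstance(ranked, pd.Series):
        genes = ranked.index.to_numpy(dtype=object)
        scores = ranked.to_numpy(dtype=float)
    else:
        genes = np.array(list(ranked.keys()), dtype=object)
        scores = np.array([ranked[g] for g in genes], dtype=float)
    if len(set(genes)) != len(genes):
        raise ValueError("ranked list contains duplicate genes")
    order = np.argsort(-scores, kind="stable")
    genes = genes[order]
    abs_scores = np.abs(scores[order])
    n = len(genes)

    members = frozenset(gene_set)
    hit_mask = np.fromiter((g in members for g in genes), dtype=bool, count=n)
    k = int(hit_mask.sum())
    if k == 0:
        raise ValueError("gene set shares no genes with the ranked list")
    if k == n:
        return GseaResult(set_name, 1.0, 1.0, k, 0, degenerate=True)

    hit_pos = np.flatnonzero(hit_mask)
    es_obs = _es_from_hits(hit_pos, abs_scores, n)

    rng = np.random.default_rng(seed)
    sign = 1.0 if es_obs >= 0 else -1.0
    same_sign = 0
    as_extreme = 0
    remaining = int(n_perm)
    chunk = max(1, min(remaining, 4_000_000 // max(n, 1)))
    while remaining > 0:
        batch = min(chunk, remaining)
        # random k-subsets via partial sort of uniform keys, one row per perm
        keys = rng.random((batch, n))
        pos = np.sort(np.argpartition(keys, k - 1, axis=1)[:, :k], axis=1)
        es_p = _es_batch(pos, abs_scores, n)
        keep = es_p * sign >= 0
        same_sign += int(keep.sum())
        as_extreme += int((keep & (np.abs(es_p) >= abs(es_obs))).sum())
        remaining -= batch
    p = (1 + as_extreme) / (1 + same_sign)
    return GseaResult(set_name, float(es_obs), float(p), k, int(n_perm))


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation on mid-ranks.

    p-value: t-approximation for n >= 10, exact permutation enumeration
    below (n <= 9 keeps the factorial enumeration small).  Two-sided.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(xa)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    rx = sps.rankdata(xa)
    ry = sps.rankdata(ya)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n >= 10:
        # t approximation, as scipy
        t = rho * math.sqrt((n - 2) / max(1.0 - rho * rho, 1e-300))
        p = 2.0 * float(sps.t.sf(abs(t), df=n - 2))
    else:
        obs = abs(rho)
        count = 0
        total = 0
        ry_c = ry - ry.mean()
        rx_c = rx - rx.mean()
        denom = math.sqrt((rx_c**2).sum() * (ry_c**2).sum())
        for perm in itertools.permutations(range(n)):
            r = float((rx_c[list(perm)] * ry_c).sum()) / denom
            total += 1
            if abs(r) >= obs - 1e-12:
                count += 1
        p = count / total
    return rho, min(p, 1.0)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``adj_(i) = min_{j >= i} p_(j) * m / j`` on sorted p-values, capped at
    1, returned in the original order.  NaNs propagate and do not count
    toward m.
    """
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError("p must be 1-D")
    finite = ~np.isnan(arr)
    vals = arr[finite]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(vals)
    out = np.full_like(arr, np.nan)
    if m:
        order = np.argsort(vals, kind="stable")
        ranked = vals[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        res = np.empty(m)
        res[order] = np.minimum(adj, 1.0)
        out[finite] = res
    return out
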
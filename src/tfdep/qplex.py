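"""TMT interactome quantification.

Mirrors a chromatin pull-down (qPLEX-RIME-style) analysis: per-channel
total-intensity normalization, bait-vs-IgG enrichment calling per
condition, and a bait-only condition contrast to detect interactome
rewiring.  Per-protein tests use a moderated two-sample t: the pooled
within-group variance is shrunk toward a prior variance shared across
proteins, with the prior degrees of freedom estimated by method of moments
(limma-style) when the protein count supports it, else fixed.

Call thresholds follow the convention |log2FC| >= 0.5 (inclusive) with
BH-adjusted p < 0.05 (strict).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy import stats as sps

from .stats import bh_adjust

__all__ = [
    "normalize_channels",
    "moderated_ttest",
    "estimate_prior_df",
    "enrichment_call",
    "condition_contrast",
]

DEFAULT_LFC_CUT = 0.5
DEFAULT_ALPHA = 0.05
DEFAULT_PRIOR_DF = 4.0
DEFAULT_PSEUDOCOUNT = 1.0


def normalize_channels(matrix: pd.DataFrame) -> pd.DataFrame:
    """Equalize channel totals to the mean pre-normalization total.

    Returns a new matrix; the applied per-channel scaling factors are
    attached as ``result.attrs["scale_factors"]``.  Idempotent.  A channel
    with zero total intensity is an error.
    """
    totals = matrix.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"channel(s) with non-positive total intensity: {bad}")
    target = float(totals.mean())
    factors = target / totals
    out = matrix * factors
    out.attrs["scale_factors"] = factors
    return out


def estimate_prior_df(variances: np.ndarray, df_resid: float) -> tuple[float, float]:
    """Method-of-moments prior (df, variance) for EB variance shrinkage.

    Models sample variances as scaled-F around a common prior variance:
    on the log scale, ``var(log s^2) = psi'(d/2) + psi'(d0/2)``.  Solves
    for d0; when the across-protein spread does not exceed what sampling
    alone explains, the prior df is infinite (full shrinkage to the mean).
    """
    v = np.asarray(variances, dtype=float)
    v = v[np.isfinite(v) & (v > 0)]
    if len(v) < 10:
        return DEFAULT_PRIOR_DF, float(np.mean(v)) if len(v) else 1.0
    z = np.log(v)
    excess = float(np.var(z, ddof=1)) - float(special.polygamma(1, df_resid / 2.0))
    e_mean = float(np.mean(z)) - float(special.digamma(df_resid / 2.0)) + math.log(
        df_resid / 2.0
    )
    if excess <= 1e-8:
        return math.inf, float(np.exp(e_mean))

    def f(d0: float) -> float:
        return float(special.polygamma(1, d0 / 2.0)) - excess

    try:
        d0 = optimize.brentq(f, 0.05, 1e6)
    except ValueError:
        return DEFAULT_PRIOR_DF, float(np.exp(e_mean))
    s0_sq = math.exp(e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    return float(d0), float(s0_sq)


def moderated_ttest(
    group_a: np.ndarray,
    group_b: np.ndarray,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Row-wise moderated two-sample t between two log-intensity blocks.

    ``group_a`` and ``group_b`` are proteins x replicates arrays on the
    log2 scale.  Pooled variances are shrunk toward the prior:
    ``s2_mod = (d * s2 + d0 * s0^2) / (d + d0)``; t has ``d + d0`` degrees
    of freedom.  ``prior_df=None`` triggers method-of-moments estimation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2:
        raise ValueError("need >= 2 replicates in the first group")
    if n2 < 1:
        raise ValueError("need >= 1 replicate in the second group")
    d = n1 + n2 - 2
    lfc = a.mean(axis=1) - b.mean(axis=1)
    ss = a.var(axis=1, ddof=1) * (n1 - 1)
    if n2 > 1:
        ss = ss + b.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / d

    if prior_df is None:
        d0, s0_sq = estimate_prior_df(s2, d)
    else:
        d0 = float(prior_df)
        pos = s2[s2 > 0]
        s0_sq = float(np.mean(pos)) if len(pos) else 1.0

    if math.isinf(d0):
        s2_mod = np.full_like(s2, s0_sq)
        df_total = 1e6
    else:
        s2_mod = (d * s2 + d0 * s0_sq) / (d + d0)
        df_total = d + d0
    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / se
    p = 2.0 * sps.t.sf(np.abs(t), df=df_total)
    p = np.where(se == 0, np.where(lfc == 0, 1.0, 0.0), p)
    return pd.DataFrame({"log2fc": lfc, "t": t, "p": p})


def _channels(design: pd.DataFrame, pulldown: str, condition: str | None) -> list[str]:
    mask = design["pulldown"] == pulldown
    if condition is not None:
        mask &= design["condition"] == condition
    return design.loc[mask, "channel_id"].tolist()


def _log_block(matrix: pd.DataFrame, channels: list[str], pseudocount: float) -> np.ndarray:
    missing = set(channels) - set(matrix.columns)
    if missing:
        raise ValueError(f"channels absent from matrix: {sorted(missing)}")
    return np.log2(matrix[channels].to_numpy(dtype=float) + pseudocount)


def _attach_calls(
    result: pd.DataFrame, matrix: pd.DataFrame, lfc_cut: float, alpha: float
) -> pd.DataFrame:
    result.insert(0, "protein_id", matrix.index.astype(str))
    result["adj_p"] = bh_adjust(result["p"].to_numpy())
    call = np.full(len(result), "unchanged", dtype=object)
    sig = result["adj_p"].to_numpy() < alpha
    call[sig & (result["log2fc"].to_numpy() >= lfc_cut)] = "enriched"
    call[sig & (result["log2fc"].to_numpy() <= -lfc_cut)] = "depleted"
    result["call"] = call
    result.attrs["lfc_cut"] = lfc_cut
    result.attrs["alpha"] = alpha
    return result


def enrichment_call(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    condition: str = "Dox",
    lfc_cut: float = DEFAULT_LFC_CUT,
    alpha: float = DEFAULT_ALPHA,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    prior_df: float | None = None,
    pool_igg: bool = False,
) -> pd.DataFrame:
    """Bait-over-IgG enrichment within one condition.

    Expects a normalized matrix (see :func:`normalize_channels`).  With
    ``pool_igg=True`` the IgG channels of both conditions form the
    reference.  Returns a per-protein table with log2fc, moderated p,
    BH-adjusted p, and a call in {enriched, depleted, unchanged}.
    """
    bait = _channels(design, "bait", condition)
    igg = _channels(design, "IgG", None if pool_igg else condition)
    if len(bait) < 2:
        raise ValueError(f"need >= 2 bait replicates in condition {condition!r}")
    if len(igg) < 1:
        raise ValueError(f"no IgG channels for condition {condition!r}")
    res = moderated_ttest(
        _log_block(matrix, bait, pseudocount),
        _log_block(matrix, igg, pseudocount),
        prior_df=prior_df,
    )
    return _attach_calls(res, matrix, lfc_cut, alpha)


def condition_contrast(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    lfc_cut: float = DEFAULT_LFC_CUT,
    alpha: float = DEFAULT_ALPHA,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Induced-vs-control contrast on bait channels (interactome rewiring).

    ``log2fc > 0`` means stronger association with the bait in the induced
    (Dox) state; calls use the same symmetric thresholds as
    :func:`enrichment_call`.
    """
    dox = _channels(design, "bait", "Dox")
    con = _channels(design, "bait", "Con")
    if len(dox) < 2 or len(con) < 2:
        raise ValueError("need >= 2 bait replicates in each condition")
    res = moderated_ttest(
        _log_block(matrix, dox, pseudocount),
        _log_block(matrix, con, pseudocount),
        prior_df=prior_df,
    )
    return _attach_calls(res, matrix, lfc_cut, alpha)
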
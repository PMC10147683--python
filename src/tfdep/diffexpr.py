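"""Minimal internal differential-expression stand-in.

Real experiments would run a dedicated DE fit (negative-binomial GLM) and
feed its exported table in through :func:`tfdep.io.read_contrast_table`;
this module exists so the integration pipeline is self-contained.  It uses
median-of-ratios size factors, log2 fold changes on pseudocounted
normalized counts, Welch's two-sample t per gene, and Benjamini-Hochberg
adjustment.  No dispersion or fold-change shrinkage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust

__all__ = ["NormalizationError", "size_factors", "contrast"]


class NormalizationError(ValueError):
    """No gene is expressed in every sample; size factors are undefined."""


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library-size factors, rescaled to geometric mean 1.

    For each sample, the factor is the median over genes (nonzero in every
    sample) of count / geometric-mean-across-samples.
    """
    mat = counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise NormalizationError(
            "no gene has a nonzero count in every sample"
        )
    ref = mat[all_nonzero]
    log_geo = np.log(ref).mean(axis=1, keepdims=True)
    ratios = ref / np.exp(log_geo)
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _cell_samples(design: pd.DataFrame, cell: tuple[str, str]) -> list[str]:
    genotype, treatment = cell
    mask = (design["genotype"] == genotype) & (design["treatment"] == treatment)
    return design.loc[mask, "sample_id"].tolist()


def contrast(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    cell_a: tuple[str, str],
    cell_b: tuple[str, str],
    pseudocount: float = 1.0,
    name: str | None = None,
) -> pd.DataFrame:
    """Per-gene contrast of factorial cell A over cell B.

    ``log2fc = mean log2(normalized + pseudocount)`` in A minus in B; p from
    Welch's t on those per-sample log values; ``adj_p`` by BH.  When both
    groups have zero variance the p-value is 1 for equal means and 0
    otherwise.  Returns a table with columns
    ``gene_id, log2fc, p, adj_p, mean_expr, contrast``.
    """
    samples_a = _cell_samples(design, cell_a)
    samples_b = _cell_samples(design, cell_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("each contrasted cell needs >= 2 replicates")
    missing = (set(samples_a) | set(samples_b)) - set(counts.columns)
    if missing:
        raise ValueError(f"design samples absent from count matrix: {sorted(missing)}")

    sf = size_factors(counts[samples_a + samples_b])
    norm = counts[samples_a + samples_b].to_numpy(dtype=float) / sf.to_numpy()
    log_norm = np.log2(norm + pseudocount)
    la = log_norm[:, : len(samples_a)]
    lb = log_norm[:, len(samples_a) :]

    mean_a = la.mean(axis=1)
    mean_b = lb.mean(axis=1)
    log2fc = mean_a - mean_b

    with np.errstate(divide="ignore", invalid="ignore"):
        t_res = sps.ttest_ind(la, lb, axis=1, equal_var=False)
    p = np.asarray(t_res.pvalue, dtype=float)
    # degenerate genes: zero variance in both groups
    var_a = la.var(axis=1, ddof=1)
    var_b = lb.var(axis=1, ddof=1)
    degen = (var_a == 0) & (var_b == 0)
    p[degen & (log2fc == 0)] = 1.0
    p[degen & (log2fc != 0)] = 0.0

    return pd.DataFrame(
        {
            "gene_id": counts.index.astype(str),
            "log2fc": log2fc,
            "p": p,
            "adj_p": bh_adjust(p),
            "mean_expr": (mean_a + mean_b) / 2.0,
            "contrast": name or f"{cell_a[0]}+{cell_a[1]}_vs_{cell_b[0]}-{cell_b[1]}",
        }
    )
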
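"""Gene categorization, the knockdown impact score, and target selection.

The impact score (IS) quantifies how a cofactor knockdown changes a gene's
response to induction: ``IS = log2FC(KD induced vs KD control) -
log2FC(control induced vs control control)``.  A negative IS means the
knockdown attenuates activation (or deepens repression); genes that are
significantly induced in the control genotype AND have IS at or below
``-log2(1.5)`` (a 1.5-fold reduction in activation) are "impaired", and
those whose promoters are co-bound by the TF and the cofactor are the
cofactor-dependent direct targets.

Thresholds are applied inclusively (<=, >=) throughout and recorded in the
output metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_FC_THRESHOLD",
    "DEFAULT_ALPHA",
    "DEFAULT_IS_CUTOFF",
    "categorize_genes",
    "impact_score",
    "filter_impaired_activation",
    "select_dependent_targets",
]

DEFAULT_FC_THRESHOLD = 1.5
DEFAULT_ALPHA = 0.05
DEFAULT_IS_CUTOFF = -math.log2(1.5)


def categorize_genes(
    contrast: pd.DataFrame,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Label each gene UP / DOWN / UNCHANGED / NOT_TESTED.

    UP: ``adj_p <= alpha`` and ``log2fc >= log2(fc_threshold)``; DOWN is the
    mirror image; genes with an undefined (NaN) p-value are NOT_TESTED.
    Returns columns ``gene_id, category`` with the thresholds attached as
    DataFrame attrs.
    """
    if fc_threshold <= 1:
        raise ValueError(f"fc_threshold must exceed 1, got {fc_threshold}")
    log2_cut = math.log2(fc_threshold)
    lfc = contrast["log2fc"].to_numpy(dtype=float)
    adj_p = contrast["adj_p"].to_numpy(dtype=float)

    category = np.full(len(contrast), "UNCHANGED", dtype=object)
    tested = ~(np.isnan(adj_p) | np.isnan(lfc))
    category[~tested] = "NOT_TESTED"
    sig = tested & (adj_p <= alpha)
    category[sig & (lfc >= log2_cut)] = "UP"
    category[sig & (lfc <= -log2_cut)] = "DOWN"

    out = pd.DataFrame({"gene_id": contrast["gene_id"].astype(str), "category": category})
    out.attrs["fc_threshold"] = fc_threshold
    out.attrs["alpha"] = alpha
    return out


def impact_score(
    contrast_scr: pd.DataFrame, contrast_kd: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene impact score: induction log2FC under knockdown minus control.

    Genes are matched by id; genes present in only one contrast are dropped
    (their count is recorded in ``attrs["n_dropped"]``).  Raises if the two
    contrasts share no genes.
    """
    scr = contrast_scr.set_index("gene_id")["log2fc"]
    kd = contrast_kd.set_index("gene_id")["log2fc"]
    common = scr.index.intersection(kd.index)
    if len(common) == 0:
        raise ValueError("the two contrasts share no gene ids")
    common = common.sort_values()
    out = pd.DataFrame(
        {
            "gene_id": common.astype(str),
            "lfc_scr": scr.loc[common].to_numpy(),
            "lfc_kd": kd.loc[common].to_numpy(),
        }
    )
    out["impact_score"] = out["lfc_kd"] - out["lfc_scr"]
    out.attrs["n_dropped"] = (len(scr) - len(common)) + (len(kd) - len(common))
    return out


def filter_impaired_activation(
    records: pd.DataFrame,
    categories: pd.DataFrame,
    is_cutoff: float = DEFAULT_IS_CUTOFF,
) -> list[str]:
    """Genes whose induction is impaired by the knockdown.

    Keeps genes categorized UP whose impact score is <= ``is_cutoff``
    (default ``-log2(1.5)``, i.e. at least a 1.5-fold reduction in
    activation).  Returns gene ids sorted by impact score ascending (most
    impaired first), ties broken by gene id.
    """
    cat = categories.set_index("gene_id")["category"]
    merged = records.set_index("gene_id")
    up_ids = cat.index[cat == "UP"]
    merged = merged.loc[merged.index.intersection(up_ids)]
    kept = merged[merged["impact_score"] <= is_cutoff]
    ordered = kept.assign(_gid=kept.index.astype(str)).sort_values(
        by=["impact_score", "_gid"], kind="stable"
    )
    return ordered.index.astype(str).tolist()


def select_dependent_targets(
    impaired: list[str], cobound_genes: set[str] | frozenset[str]
) -> list[str]:
    """Intersect impaired genes with co-bound genes, preserving IS order.

    ``impaired`` is assumed already sorted most-impaired-first (the order
    :func:`filter_impaired_activation` emits); the result keeps that order.
    """
    cb = frozenset(cobound_genes)
    return [g for g in impaired if g in cb]
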
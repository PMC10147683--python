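"""Interval-level ChIP-seq logic.

Co-occupancy uses unique-report semantics: ``intersect_unique(query,
subject)`` returns each query interval that shares >= 1 bp with any subject
interval, once, with its original coordinates (the behaviour of
``bedtools intersect -u -wa``).  Condition-specific peaks are the
presence/absence decomposition of two peak sets from the same factor.
Peaks are annotated to the nearest TSS by midpoint distance within a
window (default 10 kb) and classified as promoter / gene body / distal.

Interval search is a sorted sweep per chromosome using running maxima of
subject ends: O((n + m) log(n + m)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import GeneModel, GenomicInterval, PeakSet

__all__ = [
    "DEFAULT_WINDOW",
    "DEFAULT_PROMOTER_HALFWIDTH",
    "intersect_unique",
    "subtract_unique",
    "condition_specific_peaks",
    "annotate",
    "classify_context",
    "cobound_gene_set",
]

DEFAULT_WINDOW = 10_000
DEFAULT_PROMOTER_HALFWIDTH = 3_000


def _overlap_mask(query: PeakSet, subject: PeakSet) -> np.ndarray:
    """Boolean mask over query intervals: overlaps >= 1 subject interval."""
    mask = np.zeros(len(query), dtype=bool)
    subj: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, starts, ends, _ in subject.by_chrom():
        order = np.argsort(starts, kind="stable")
        starts = starts[order]
        # running max of ends lets a single binary search answer
        # "does any subject starting before q.end reach past q.start?"
        cummax_ends = np.maximum.accumulate(ends[order])
        subj[chrom] = (starts, cummax_ends)
    for chrom, q_starts, q_ends, q_idx in query.by_chrom():
        if chrom not in subj:
            continue
        s_starts, s_cummax = subj[chrom]
        # subjects with start < q.end
        pos = np.searchsorted(s_starts, q_ends, side="left")
        has = pos > 0
        hit = np.zeros(len(q_idx), dtype=bool)
        hit[has] = s_cummax[pos[has] - 1] > q_starts[has]
        mask[q_idx] = hit
    return mask


def intersect_unique(query: PeakSet, subject: PeakSet) -> PeakSet:
    """Query intervals overlapping >= 1 subject interval (original coords)."""
    mask = _overlap_mask(query, subject)
    return query.select(np.flatnonzero(mask))


def subtract_unique(query: PeakSet, subject: PeakSet) -> PeakSet:
    """Query intervals with zero overlap against the subject set."""
    mask = _overlap_mask(query, subject)
    return query.select(np.flatnonzero(~mask))


def condition_specific_peaks(
    set_a: PeakSet, set_b: PeakSet
) -> tuple[PeakSet, PeakSet, PeakSet]:
    """Presence/absence decomposition of two conditions of one factor.

    Returns ``(a_only, b_only, common)`` where ``a_only`` are A peaks with
    no overlap in B (e.g. peaks lost upon knockdown when A is the control
    condition), ``b_only`` the reverse, and ``common`` the A peaks that
    overlap B.  The three cover A ∪ B by construction.
    """
    a_only = subtract_unique(set_a, set_b)
    b_only = subtract_unique(set_b, set_a)
    common = intersect_unique(set_a, set_b)
    return a_only, b_only, common


@dataclass(frozen=True)
class PeakAnnotation:
    """One peak's nearest-TSS assignment and genomic context."""

    interval: GenomicInterval
    gene_id: str | None
    signed_distance: int | None  # midpoint - TSS, genomic orientation
    context: str  # promoter | gene_body | distal


def _gene_arrays(genes: Sequence[GeneModel]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
    out = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        out[chrom] = (
            np.asarray([p[0] for p in pairs], dtype=np.int64),
            np.asarray([p[1] for p in pairs], dtype=object),
        )
    return out


def annotate(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    window: int = DEFAULT_WINDOW,
    promoter_halfwidth: int = DEFAULT_PROMOTER_HALFWIDTH,
    gene_spans: pd.DataFrame | None = None,
) -> list[PeakAnnotation]:
    """Assign each peak to the nearest TSS within ``window`` bp.

    Distance is measured from the peak midpoint ``floor((start + end) / 2)``
    to the TSS; the signed distance is in genomic orientation (positive
    when the midpoint lies 3' of the TSS in coordinate space).  Exactly
    equidistant TSSs resolve to the lexicographically smaller gene id.
    Context is classified per :func:`classify_context`.
    """
    if not genes:
        raise ValueError("gene models must be non-empty")
    gene_arr = _gene_arrays(genes)
    annotations: list[PeakAnnotation] = []
    for iv in peaks:
        mid = iv.midpoint
        gene_id: str | None = None
        signed: int | None = None
        if iv.chrom in gene_arr:
            tss, ids = gene_arr[iv.chrom]
            j = int(np.searchsorted(tss, mid))
            candidates: list[tuple[int, str, int]] = []
            if j > 0:
                candidates.append((abs(mid - int(tss[j - 1])), str(ids[j - 1]), int(tss[j - 1])))
            if j < len(tss):
                candidates.append((abs(mid - int(tss[j])), str(ids[j]), int(tss[j])))
            if candidates:
                best = min(candidates)  # (distance, gene_id) lexicographic tie-break
                if best[0] <= window:
                    gene_id = best[1]
                    signed = mid - best[2]
        context = classify_context(
            iv, genes_arr=gene_arr, promoter_halfwidth=promoter_halfwidth,
            gene_spans=gene_spans,
        )
        annotations.append(PeakAnnotation(iv, gene_id, signed, context))
    return annotations


def classify_context(
    interval: GenomicInterval,
    genes: Sequence[GeneModel] | None = None,
    promoter_halfwidth: int = DEFAULT_PROMOTER_HALFWIDTH,
    gene_spans: pd.DataFrame | None = None,
    genes_arr: dict | None = None,
) -> str:
    """Promoter / gene-body / distal classification of one interval.

    Promoter: midpoint within ``TSS +/- promoter_halfwidth`` of any gene.
    Gene body: midpoint inside any provided gene span (optional DataFrame
    with columns ``chrom, start, end``).  Otherwise distal.
    """
    if genes_arr is None:
        if genes is None:
            raise ValueError("provide gene models")
        genes_arr = _gene_arrays(genes)
    mid = interval.midpoint
    if interval.chrom in genes_arr:
        tss, _ = genes_arr[interval.chrom]
        j = int(np.searchsorted(tss, mid))
        for k in (j - 1, j):
            if 0 <= k < len(tss) and abs(mid - int(tss[k])) <= promoter_halfwidth:
                return "promoter"
    if gene_spans is not None and len(gene_spans):
        rows = gene_spans[gene_spans["chrom"] == interval.chrom]
        inside = (rows["start"].to_numpy() <= mid) & (mid < rows["end"].to_numpy())
        if inside.any():
            return "gene_body"
    return "distal"


def annotation_table(annotations: Iterable[PeakAnnotation]) -> pd.DataFrame:
    """Flatten annotations into a TSV-ready table."""
    rows = []
    for a in annotations:
        rows.append(
            {
                "chrom": a.interval.chrom,
                "start": a.interval.start,
                "end": a.interval.end,
                "name": a.interval.name,
                "gene_id": a.gene_id if a.gene_id is not None else ".",
                "signed_distance": a.signed_distance if a.signed_distance is not None else ".",
                "context": a.context,
            }
        )
    return pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "name", "gene_id", "signed_distance", "context",
    ])


def cobound_gene_set(
    factor1: PeakSet,
    factor2: PeakSet,
    genes: Sequence[GeneModel],
    window: int = DEFAULT_WINDOW,
) -> frozenset[str]:
    """Genes whose annotated peaks are co-bound by both factors.

    Co-occupancy is asymmetric at the peak level (query coordinates are
    reported), so the gene-level set unions both query directions to make
    the result symmetric in its arguments.
    """
    ids: set[str] = set()
    for query, subject in ((factor1, factor2), (factor2, factor1)):
        cobound = intersect_unique(query, subject)
        for ann in annotate(cobound, genes, window=window):
            if ann.gene_id is not None:
                ids.add(ann.gene_id)
    return frozenset(ids)
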
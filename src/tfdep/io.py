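"""Readers and writers for the tabular and genomic formats the pipeline touches.

All genomic coordinates are 0-based, half-open ``[start, end)`` throughout the
package; nothing here converts to 1-based display.  The TSV dialect is
tab-separated, UTF-8, ``.`` for missing values, no quoting.  Every reader
validates its input and raises :class:`ParseError` (with a line number where
one makes sense) rather than silently coercing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "GenomicInterval",
    "PeakSet",
    "GeneModel",
    "GeneSetCollection",
    "read_bed",
    "write_bed",
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
    "read_gene_models",
    "write_gene_models",
    "read_gmt",
    "write_gmt",
    "read_tmt",
    "write_tmt",
    "read_channel_design",
    "write_channel_design",
    "read_contrast_table",
    "write_contrast_table",
]

TSV_NA = "."


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# genomic types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    ``start < end`` and ``start >= 0`` are enforced at construction.
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval: [{self.start}, {self.end})"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """>=1 shared bp under half-open semantics."""
        return self.chrom == other.chrom and max(
            self.start, other.start
        ) < min(self.end, other.end)


class PeakSet:
    """An immutable, sorted collection of genomic intervals.

    Intervals are grouped by chromosome and sorted by ``(start, end)``.
    Opaque extra BED columns (e.g. narrowPeak statistics) survive a
    read -> write -> read round trip untouched.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval],
        extra: Sequence[Sequence[str]] | None = None,
    ):
        ivs = list(intervals)
        if extra is not None and len(extra) != len(ivs):
            raise ValueError("extra payload length must match interval count")
        payload = list(extra) if extra is not None else [()] * len(ivs)
        order = sorted(
            range(len(ivs)),
            key=lambda i: (ivs[i].chrom, ivs[i].start, ivs[i].end, ivs[i].name),
        )
        self._intervals: tuple[GenomicInterval, ...] = tuple(ivs[i] for i in order)
        self._extra: tuple[tuple[str, ...], ...] = tuple(
            tuple(payload[i]) for i in order
        )

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self._intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return self._intervals == other._intervals and self._extra == other._extra

    def __repr__(self) -> str:
        return f"PeakSet({len(self)} intervals on {len(self.chroms())} chromosomes)"

    @property
    def intervals(self) -> tuple[GenomicInterval, ...]:
        return self._intervals

    @property
    def extra(self) -> tuple[tuple[str, ...], ...]:
        return self._extra

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self._intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)

    def by_chrom(self) -> Iterator[tuple[str, np.ndarray, np.ndarray, np.ndarray]]:
        """Yield ``(chrom, starts, ends, indices)`` with arrays sorted by start.

        ``indices`` index into :attr:`intervals`, so callers can map matches
        back to the original intervals and payload.
        """
        chrom_rows: dict[str, list[int]] = {}
        for i, iv in enumerate(self._intervals):
            chrom_rows.setdefault(iv.chrom, []).append(i)
        for chrom, rows in chrom_rows.items():
            idx = np.asarray(rows, dtype=np.intp)
            starts = np.asarray([self._intervals[i].start for i in rows], dtype=np.int64)
            ends = np.asarray([self._intervals[i].end for i in rows], dtype=np.int64)
            yield chrom, starts, ends, idx

    def select(self, indices: Iterable[int]) -> "PeakSet":
        rows = sorted(set(int(i) for i in indices))
        return PeakSet(
            [self._intervals[i] for i in rows],
            extra=[self._extra[i] for i in rows],
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene anchor for peak annotation: id, chromosome, strand and TSS."""

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError(f"negative TSS: {self.tss}")


class GeneSetCollection:
    """Named gene sets with an optional explicit universe.

    Invariants: no empty set; when a universe is given it contains every
    member of every set.
    """

    def __init__(
        self,
        sets: Mapping[str, Iterable[str]],
        universe: Iterable[str] | None = None,
    ):
        self._sets: dict[str, frozenset[str]] = {}
        for name, members in sets.items():
            fs = frozenset(members)
            if not fs:
                raise ValueError(f"gene set {name!r} is empty")
            self._sets[name] = fs
        self._universe: frozenset[str] | None = (
            frozenset(universe) if universe is not None else None
        )
        if self._universe is not None:
            for name, fs in self._sets.items():
                stray = fs - self._universe
                if stray:
                    raise ValueError(
                        f"gene set {name!r} has members outside the universe: "
                        f"{sorted(stray)[:5]}"
                    )

    @property
    def universe(self) -> frozenset[str] | None:
        return self._universe

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self._sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def items(self) -> Iterable[tuple[str, frozenset[str]]]:
        return self._sets.items()


# ---------------------------------------------------------------------------
# BED / narrowPeak
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> PeakSet:
    """Read BED3-6 or narrowPeak into a :class:`PeakSet`.

    Columns beyond the sixth are preserved verbatim as opaque payload and
    written back by :func:`write_bed`.  Malformed coordinates raise
    :class:`ParseError` naming the offending line.
    """
    intervals: list[GenomicInterval] = []
    extras: list[tuple[str, ...]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns")
            chrom = fields[0]
            try:
                start = int(fields[1])
                end = int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            if start < 0:
                raise ParseError(f"{path}:{lineno}: negative start {start}")
            if start >= end:
                raise ParseError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            name = fields[3] if len(fields) > 3 else "."
            score = 0.0
            if len(fields) > 4 and fields[4] != TSV_NA:
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad score") from exc
            intervals.append(GenomicInterval(chrom, start, end, name, score))
            extras.append(tuple(fields[5:]))
    return PeakSet(intervals, extra=extras)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    """Write a :class:`PeakSet` as BED; extra payload columns follow column 5."""
    with open(path, "w", encoding="utf-8") as fh:
        for iv, extra in zip(peaks.intervals, peaks.extra):
            cols = [iv.chrom, str(iv.start), str(iv.end), iv.name, _fmt_score(iv.score)]
            cols.extend(extra)
            fh.write("\t".join(cols) + "\n")


def _fmt_score(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


# ---------------------------------------------------------------------------
# tabular readers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[TSV_NA], keep_default_na=False)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(
            f"{path}: missing required column(s) {missing}; "
            f"expected header with {list(required)}"
        )


def read_counts(path: str | Path) -> tuple[pd.DataFrame, list[str]]:
    """Read a gene x sample count matrix.

    First column is the gene id; remaining columns are samples.  Counts must
    be non-negative integers.  Returns ``(matrix, sample_ids)`` with the gene
    id as index.
    """
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need a gene-id column plus >=1 sample column")
    gene_col = df.columns[0]
    if df[gene_col].duplicated().any():
        dups = df.loc[df[gene_col].duplicated(), gene_col].tolist()[:5]
        raise ParseError(f"{path}: duplicate gene ids {dups}")
    mat = df.set_index(gene_col)
    for col in mat.columns:
        vals = pd.to_numeric(mat[col], errors="coerce")
        if vals.isna().any():
            raise ParseError(f"{path}: non-numeric count in column {col!r}")
        if (vals < 0).any():
            raise ParseError(f"{path}: negative count in column {col!r}")
        if not np.allclose(vals, np.round(vals)):
            raise ParseError(f"{path}: non-integer count in column {col!r}")
        mat[col] = vals.astype(np.int64)
    mat.index = mat.index.astype(str)
    mat.index.name = "gene_id"
    return mat, [str(c) for c in mat.columns]


def write_counts(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


DESIGN_COLUMNS = ("sample_id", "genotype", "treatment", "replicate")


def read_design(path: str | Path) -> pd.DataFrame:
    """Read the 2x2 factorial sample design (genotype x treatment)."""
    df = _read_tsv(path)
    _require_columns(df, DESIGN_COLUMNS, path)
    if df["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample ids")
    bad_g = set(df["genotype"]) - {"SCR", "KD"}
    if bad_g:
        raise ParseError(f"{path}: unknown genotype value(s) {sorted(bad_g)}")
    bad_t = set(df["treatment"]) - {"Con", "Dox"}
    if bad_t:
        raise ParseError(f"{path}: unknown treatment value(s) {sorted(bad_t)}")
    df = df.astype({"sample_id": str, "genotype": str, "treatment": str})
    df["replicate"] = df["replicate"].astype(int)
    return df


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read a gene-model TSV (gene_id, chrom, strand, tss; 0-based TSS)."""
    df = _read_tsv(path)
    _require_columns(df, ("gene_id", "chrom", "strand", "tss"), path)
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()[:5]
        raise ParseError(f"{path}: duplicate gene ids {dups}")
    models = []
    for row in df.itertuples(index=False):
        try:
            models.append(
                GeneModel(str(row.gene_id), str(row.chrom), str(row.strand), int(row.tss))
            )
        except ValueError as exc:
            raise ParseError(f"{path}: gene {row.gene_id!r}: {exc}") from exc
    return models


def write_gene_models(models: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\n")
        for m in models:
            fh.write(f"{m.gene_id}\t{m.chrom}\t{m.strand}\t{m.tss}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets in GMT format (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 member"
                )
            name = fields[0]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = [g for g in fields[2:] if g]
            if not members:
                raise ParseError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = members
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.items():
            fh.write("\t".join([name, TSV_NA] + sorted(members)) + "\n")


def read_tmt(path: str | Path) -> tuple[pd.DataFrame, list[str]]:
    """Read a protein x channel TMT intensity matrix (non-negative reals)."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need a protein-id column plus >=1 channel")
    pid = df.columns[0]
    if df[pid].duplicated().any():
        raise ParseError(f"{path}: duplicate protein ids")
    mat = df.set_index(pid)
    for col in mat.columns:
        vals = pd.to_numeric(mat[col], errors="coerce")
        if vals.isna().any():
            raise ParseError(f"{path}: non-numeric intensity in column {col!r}")
        if (vals < 0).any():
            raise ParseError(f"{path}: negative intensity in column {col!r}")
        mat[col] = vals.astype(float)
    mat.index = mat.index.astype(str)
    mat.index.name = "protein_id"
    return mat, [str(c) for c in mat.columns]


def write_tmt(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="protein_id")


CHANNEL_COLUMNS = ("channel_id", "pulldown", "condition", "replicate")


def read_channel_design(path: str | Path) -> pd.DataFrame:
    """Read the TMT channel design (bait/IgG pulldown x Con/Dox condition)."""
    df = _read_tsv(path)
    _require_columns(df, CHANNEL_COLUMNS, path)
    if df["channel_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate channel ids")
    bad_p = set(df["pulldown"]) - {"bait", "IgG"}
    if bad_p:
        raise ParseError(f"{path}: unknown pulldown value(s) {sorted(bad_p)}")
    bad_c = set(df["condition"]) - {"Con", "Dox"}
    if bad_c:
        raise ParseError(f"{path}: unknown condition value(s) {sorted(bad_c)}")
    df = df.astype({"channel_id": str, "pulldown": str, "condition": str})
    df["replicate"] = df["replicate"].astype(int)
    return df


def write_channel_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index=False)


CONTRAST_COLUMNS = ("gene_id", "log2fc", "p", "adj_p")


def read_contrast_table(path: str | Path) -> pd.DataFrame:
    """Read a per-contrast differential-expression table.

    This is the adapter for externally produced tables (e.g. a DESeq2
    export): required columns ``gene_id, log2fc, p, adj_p``; any additional
    columns are preserved.
    """
    df = _read_tsv(path)
    _require_columns(df, CONTRAST_COLUMNS, path)
    if df["gene_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate gene ids")
    df["gene_id"] = df["gene_id"].astype(str)
    for col in ("log2fc", "p", "adj_p"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    for col in ("p", "adj_p"):
        vals = df[col].dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise ParseError(f"{path}: {col} outside [0, 1]")
    return df


def write_contrast_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep=TSV_NA)
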
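"""Genomic data model and interval algebra.

All coordinates are 0-based, half-open (BED convention).  Collections of
intervals and tags are plain :class:`pandas.DataFrame` objects with
lower-case column names (``chrom``, ``start``, ``end`` / ``chrom``, ``pos``,
``strand``); scalar intervals are :class:`Interval` named tuples.  The
interval algebra is backed by :mod:`pyranges`.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
import pyranges as pr

__all__ = [
    "Interval",
    "GenomeLayout",
    "read_chrom_sizes",
    "read_tags",
    "write_tags",
    "read_bed",
    "write_bed",
    "merge_intervals",
    "intersect_intervals",
    "subtract_intervals",
    "overlaps_any",
    "sort_intervals",
]

INTERVAL_COLUMNS = ["chrom", "start", "end"]
TAG_COLUMNS = ["chrom", "pos", "strand"]


class Interval(NamedTuple):
    """Half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


class GenomeLayout:
    """Chromosome name -> length table; carries the genome size G."""

    def __init__(self, chrom_sizes: Mapping[str, int]):
        if not chrom_sizes:
            raise ValueError("empty chromosome size table")
        for chrom, size in chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"non-positive length for chromosome {chrom!r}")
        self.chrom_sizes: dict[str, int] = dict(chrom_sizes)

    @property
    def genome_size(self) -> int:
        return sum(self.chrom_sizes.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_sizes

    def __getitem__(self, chrom: str) -> int:
        return self.chrom_sizes[chrom]

    def clip(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Clip ``[start, end)`` to the chromosome bounds."""
        size = self.chrom_sizes[chrom]
        return max(0, start), min(size, end)

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "GenomeLayout":
        return cls(read_chrom_sizes(path))


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` table (UCSC chrom.sizes)."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'chrom length'")
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad length {fields[1]!r}") from exc
    return sizes


def _empty_intervals() -> pd.DataFrame:
    return pd.DataFrame({"chrom": pd.Series(dtype=object),
                         "start": pd.Series(dtype=np.int64),
                         "end": pd.Series(dtype=np.int64)})


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def read_tags(path: str | os.PathLike, layout: GenomeLayout | None = None) -> pd.DataFrame:
    """Read aligned tags from a BED-like file into ``(chrom, pos, strand)``.

    ``pos`` is the 0-based 5' coordinate of the read: ``start`` on the
    forward strand, ``end - 1`` on the reverse strand.  Output is sorted by
    ``(chrom, pos)``.
    """
    chroms: list[str] = []
    positions: list[int] = []
    strands: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or end <= start:
                raise ValueError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            strand = fields[5] if len(fields) >= 6 else "+"
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: strand must be '+' or '-', got {strand!r}")
            if layout is not None and chrom not in layout:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            chroms.append(chrom)
            positions.append(start if strand == "+" else end - 1)
            strands.append(strand)
    tags = pd.DataFrame({"chrom": chroms, "pos": positions, "strand": strands})
    return tags.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def write_tags(tags: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write tags as 1-bp BED6 records so that ``read_tags`` round-trips."""
    with open(path, "w") as fh:
        for i, row in enumerate(tags.itertuples(index=False)):
            fh.write(f"{row.chrom}\t{row.pos}\t{row.pos + 1}\ttag_{i + 1}\t0\t{row.strand}\n")


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read a 3+ column BED file into a ``(chrom, start, end[, ...])`` frame."""
    rows = []
    extra_cols: int = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                rows.append((fields[0], int(fields[1]), int(fields[2]), *fields[3:6]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            extra_cols = max(extra_cols, len(fields[3:6]))
    if not rows:
        return _empty_intervals()
    names = INTERVAL_COLUMNS + ["name", "score", "strand"][:extra_cols]
    df = pd.DataFrame([r + ("",) * (len(names) - len(r)) for r in rows], columns=names)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return sort_intervals(df)


def write_bed(intervals: pd.DataFrame, path: str | os.PathLike,
              name_prefix: str = "region",
              score_col: str | None = None,
              extra_cols: Iterable[str] = ()) -> None:
    """Write intervals as tab-separated BED.

    Column 4 is ``<name_prefix>_<i>``; ``score_col`` (if given) fills column
    5; a ``strand`` column (if present) fills column 6; ``extra_cols`` are
    appended after the standard six.
    """
    extra_cols = list(extra_cols)
    with open(path, "w") as fh:
        for i, row in enumerate(intervals.itertuples(index=False)):
            fields = [str(row.chrom), str(int(row.start)), str(int(row.end)),
                      f"{name_prefix}_{i + 1}"]
            if score_col is not None or "strand" in intervals.columns or extra_cols:
                score = getattr(row, score_col) if score_col else 0
                fields.append(str(score))
                fields.append(str(getattr(row, "strand", ".")))
            fields.extend(str(getattr(row, c)) for c in extra_cols)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Interval algebra (pyranges-backed)
# ---------------------------------------------------------------------------

def _to_ranges(df: pd.DataFrame) -> pr.PyRanges:
    return pr.PyRanges(chromosomes=df["chrom"].astype(str),
                       starts=df["start"].astype(np.int64),
                       ends=df["end"].astype(np.int64))


def _from_ranges(gr: pr.PyRanges) -> pd.DataFrame:
    if gr.empty:
        return _empty_intervals()
    df = gr.df.rename(columns={"Chromosome": "chrom", "Start": "start", "End": "end"})
    df["chrom"] = df["chrom"].astype(str)
    return sort_intervals(df[INTERVAL_COLUMNS])


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Disjoint sorted union of (possibly overlapping) intervals."""
    if len(df) == 0:
        return _empty_intervals()
    return _from_ranges(_to_ranges(df).merge())


def intersect_intervals(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    if len(a) == 0 or len(b) == 0:
        return _empty_intervals()
    return _from_ranges(_to_ranges(a).intersect(_to_ranges(b)))


def subtract_intervals(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Parts of ``a`` not covered by ``b`` (half-open semantics)."""
    if len(a) == 0:
        return _empty_intervals()
    if len(b) == 0:
        return sort_intervals(a[INTERVAL_COLUMNS].copy())
    return _from_ranges(_to_ranges(a).subtract(_to_ranges(b)))


def overlaps_any(a: pd.DataFrame, b: pd.DataFrame) -> np.ndarray:
    """Boolean per interval of ``a``: does it share >= 1 bp with any of ``b``?"""
    if len(a) == 0:
        return np.zeros(0, dtype=bool)
    if len(b) == 0:
        return np.zeros(len(a), dtype=bool)
    gr = _to_ranges(a)
    gr.row = np.arange(len(a))
    counts = gr.count_overlaps(_to_ranges(b))
    out = np.zeros(len(a), dtype=bool)
    cdf = counts.df
    out[cdf["row"].to_numpy()] = cdf["NumberOverlaps"].to_numpy() > 0
    return out
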
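"""Genomic interval algebra and BED input/output.

All coordinates are 0-based, half-open (the BED convention): an interval
``[start, end)`` covers bases ``start`` .. ``end - 1``.  Strand is carried on
intervals but ignored by the overlap operations here — ATAC-seq peaks are
unstranded; strand only matters for promoter windows and motif scanning,
which live in other modules.

Chromosomes are ordered lexicographically everywhere, so outputs are stable
across runs and platforms.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CATEGORIES_STRAND = (".", "+", "-")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval on a named sequence.

    Parameters
    ----------
    chrom : str
        Sequence (chromosome) name; must be non-empty.
    start, end : int
        0-based half-open coordinates with ``0 <= start < end``.
    name : str
        Free-form identifier (peak id, gene id, ...). May be empty.
    score : float
        BED score column; semantics are caller-defined.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    name: str = ""
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in CATEGORIES_STRAND:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared bases with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.name)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval` with a track label.

    Intervals are kept sorted by (chrom, start, end, name).  Duplicate
    intervals are permitted but flagged with a warning when loaded from BED.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), label: str = ""):
        self.label = label
        self.intervals: list[GenomicInterval] = sorted(intervals, key=GenomicInterval.sort_key)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __repr__(self) -> str:
        return f"IntervalSet(label={self.label!r}, n={len(self)})"

    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def total_bases(self) -> int:
        """Number of bases covered (overlaps counted once)."""
        return sum(iv.length for iv in merge(self))

    def with_names(self, prefix: str) -> "IntervalSet":
        """Return a copy where every interval is named ``prefix_<i>``."""
        named = [
            replace(iv, name=f"{prefix}_{i:05d}") for i, iv in enumerate(self.intervals)
        ]
        return IntervalSet(named, label=self.label)


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, label: str | None = None) -> IntervalSet:
    """Read a BED3/BED6 file into an :class:`IntervalSet`.

    Track/browser/comment lines are tolerated and skipped.  Malformed lines
    raise :class:`ValueError` naming the offending line number.  Duplicate
    intervals are kept but logged.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            try:
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
                name = fields[3] if len(fields) > 3 else ""
                score = float(fields[4]) if len(fields) > 4 and fields[4] not in (".", "") else 0.0
                strand = fields[5] if len(fields) > 5 else "."
                intervals.append(GenomicInterval(chrom, start, end, name, score, strand))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line: {exc}") from exc
    dupes = [k for k, v in Counter((iv.chrom, iv.start, iv.end) for iv in intervals).items() if v > 1]
    if dupes:
        logger.warning("%s: %d duplicate interval(s), e.g. %s", path, len(dupes), dupes[0])
    return IntervalSet(intervals, label=label if label is not None else path.stem)


def write_bed(intervals: IntervalSet | Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED6 (tab-separated, no header)."""
    with open(path, "w") as fh:
        for iv in intervals:
            score = f"{iv.score:g}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def intersect(
    a: IntervalSet,
    b: IntervalSet,
    min_overlap: int = 1,
) -> list[tuple[GenomicInterval, GenomicInterval, int]]:
    """All pairs of intervals from ``a`` and ``b`` sharing >= ``min_overlap`` bases.

    Returns tuples ``(a_interval, b_interval, overlap_bp)`` ordered by
    (chrom, a.start, b.start).  The default ``min_overlap=1`` matches the
    bedtools single-shared-base criterion.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    pairs: list[tuple[GenomicInterval, GenomicInterval, int]] = []
    a_by = a.by_chrom()
    b_by = b.by_chrom()
    for chrom in sorted(set(a_by) & set(b_by)):
        av = a_by[chrom]
        bv = b_by[chrom]
        a_start = np.array([iv.start for iv in av])
        a_end = np.array([iv.end for iv in av])
        b_start = np.array([iv.start for iv in bv])
        b_end = np.array([iv.end for iv in bv])
        # b intervals sorted by start; for each a, candidates have
        # b.start < a.end and b.end > a.start
        hi = np.searchsorted(b_start, a_end, side="left")
        for i in range(len(av)):
            if hi[i] == 0:
                continue
            ov = np.minimum(a_end[i], b_end[: hi[i]]) - np.maximum(a_start[i], b_start[: hi[i]])
            for j in np.nonzero(ov >= min_overlap)[0]:
                pairs.append((av[i], bv[j], int(ov[j])))
    pairs.sort(key=lambda t: (t[0].chrom, t[0].start, t[1].start, t[0].name, t[1].name))
    return pairs


def merge(a: IntervalSet, max_gap: int = 0) -> IntervalSet:
    """Minimal set of non-overlapping intervals covering the same bases.

    Intervals separated by at most ``max_gap`` bases are joined: under the
    half-open convention the gap between ``[s1, e1)`` and ``[s2, e2)`` with
    ``s2 >= e1`` is ``s2 - e1``.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    merged: list[GenomicInterval] = []
    for chrom, ivs in sorted(a.by_chrom().items()):
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_end <= max_gap:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return IntervalSet(merged, label=a.label)


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Bases of ``a`` not covered by ``b``; intervals of ``a`` may split.

    Name, score and strand of the source interval are carried onto each
    remnant.  Intervals fully covered by ``b`` disappear.
    """
    b_merged = merge(b).by_chrom() if len(b) else {}
    out: list[GenomicInterval] = []
    for iv in a:
        blockers = b_merged.get(iv.chrom, [])
        cursor = iv.start
        for blk in blockers:
            if blk.end <= cursor or blk.start >= iv.end:
                continue
            if blk.start > cursor:
                out.append(replace(iv, start=cursor, end=blk.start))
            cursor = max(cursor, blk.end)
            if cursor >= iv.end:
                break
        if cursor < iv.end:
            out.append(replace(iv, start=cursor, end=iv.end))
    return IntervalSet(out, label=a.label)


def overlap_counts(sets: Sequence[IntervalSet]) -> tuple[pd.DataFrame, dict[tuple[bool, ...], int]]:
    """Membership of merged union intervals across several peak sets.

    For every interval of the merged union of all inputs, reports a
    presence/absence vector (>=1 bp overlap) per input set, plus summary
    counts for each region of the Venn partition.

    Returns
    -------
    table : pandas.DataFrame
        Columns ``chrom, start, end`` plus one boolean column per set label.
    venn : dict
        Maps membership tuples (ordered as the input sets) to the number of
        union intervals with that pattern.
    """
    if len(sets) < 2:
        raise ValueError("overlap_counts requires at least two interval sets")
    labels = [s.label or f"set{i}" for i, s in enumerate(sets)]
    if len(set(labels)) != len(labels):
        labels = [f"{lab}_{i}" for i, lab in enumerate(labels)]
    union = merge(IntervalSet(itertools.chain.from_iterable(sets), label="union"))
    membership = np.zeros((len(union), len(sets)), dtype=bool)
    index = {(iv.chrom, iv.start, iv.end): i for i, iv in enumerate(union)}
    for j, s in enumerate(sets):
        for u, _, _ in intersect(union, s):
            membership[index[(u.chrom, u.start, u.end)], j] = True
    table = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in union],
            "start": [iv.start for iv in union],
            "end": [iv.end for iv in union],
        }
    )
    for j, lab in enumerate(labels):
        table[lab] = membership[:, j]
    venn = Counter(tuple(row) for row in membership)
    return table, dict(venn)
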
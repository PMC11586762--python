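"""Genomic intervals (0-based half-open) and the interval algebra the
filter tracks rely on: normalization, merging, complement, membership."""

from __future__ import annotations

import gzip
import logging
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .keys import normalize_chrom

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "normalize_intervals",
    "complement_intervals",
    "read_interval_track",
    "write_bed",
    "IntervalIndex",
]


_CHROM_ORDER = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25}


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    c = normalize_chrom(chrom)
    return (_CHROM_ORDER.get(c, 99), c)


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start >= self.end:
            raise ValueError(f"empty interval: {self.chrom}:{self.start}-{self.end}")
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")

    def __len__(self) -> int:
        return self.end - self.start


def normalize_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Sort and merge overlapping or book-ended intervals. Idempotent."""
    by_pos = sorted(intervals, key=lambda iv: (chrom_sort_key(iv.chrom), iv.start, iv.end))
    out: list[GenomicInterval] = []
    for iv in by_pos:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def complement_intervals(
    intervals: Sequence[GenomicInterval], chrom_lengths: Mapping[str, int]
) -> list[GenomicInterval]:
    """Complement of a normalized track over the given chromosome lengths."""
    track = normalize_intervals(intervals)
    out: list[GenomicInterval] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in track:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(chrom_lengths, key=chrom_sort_key):
        length = chrom_lengths[chrom]
        cursor = 0
        for iv in by_chrom.get(normalize_chrom(chrom), []):
            if iv.start > cursor:
                out.append(GenomicInterval(chrom, cursor, min(iv.start, length)))
            cursor = max(cursor, iv.end)
        if cursor < length:
            out.append(GenomicInterval(chrom, cursor, length))
    return out


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_interval_track(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file into a normalized (sorted, merged) track.

    Rows with start >= end are rejected; the rejection count is logged.
    """
    intervals: list[GenomicInterval] = []
    rejected = 0
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                rejected += 1
                continue
            intervals.append(GenomicInterval(chrom, start, end))
    if rejected:
        logger.warning("rejected %d BED rows with start >= end in %s", rejected, path)
    return normalize_intervals(intervals)


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path, names: Iterable[str] | None = None) -> None:
    names_list = list(names) if names is not None else None
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if names_list is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{names_list[i]}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


class IntervalIndex:
    """Bisect-backed membership queries against a normalized track."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for iv in normalize_intervals(intervals):
            self._starts.setdefault(iv.chrom, []).append(iv.start)
            self._ends.setdefault(iv.chrom, []).append(iv.end)

    def contains(self, chrom: str, pos0: int) -> bool:
        """Is 0-based position inside the track?"""
        chrom = normalize_chrom(chrom)
        starts = self._starts.get(chrom)
        if not starts:
            return False
        i = bisect_right(starts, pos0) - 1
        return i >= 0 and pos0 < self._ends[chrom][i]

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """Does [start, end) intersect the track?"""
        chrom = normalize_chrom(chrom)
        starts = self._starts.get(chrom)
        if not starts:
            return False
        i = bisect_right(starts, end - 1) - 1
        return i >= 0 and start < self._ends[chrom][i]
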
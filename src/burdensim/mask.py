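"""Low-complexity masking: symmetric DUST, homopolymer runs, and the merged
and padded filter track.

The DUST score of an interval of length L is 10 * sum_t c_t*(c_t - 1)/2
over its triplet counts c_t, divided by (L - 3).  An interval is reported
when its score meets the threshold; the output is the merged union of all
qualifying intervals (capped at the window length), which is symmetric
under sequence reversal and shrinks monotonically as the threshold rises.
Runs of N break candidate windows and are never masked by DUST.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .intervals import GenomicInterval, normalize_intervals

__all__ = [
    "dust_score",
    "sdust_intervals",
    "homopolymer_intervals",
    "MaskTrack",
    "build_mask_track",
]

_TRIPLET_BASES = {"A": 0, "C": 1, "G": 2, "T": 3}


def dust_score(segment: str) -> float:
    """DUST score of one interval (0 when shorter than 4 bases)."""
    L = len(segment)
    if L < 4:
        return 0.0
    counts: dict[int, int] = {}
    total = 0
    for i in range(L - 2):
        t = (
            (_TRIPLET_BASES[segment[i]] << 4)
            | (_TRIPLET_BASES[segment[i + 1]] << 2)
            | _TRIPLET_BASES[segment[i + 2]]
        )
        c = counts.get(t, 0)
        total += c  # sum c*(c-1)/2 built incrementally
        counts[t] = c + 1
    return 10.0 * total / (L - 3)


def _segment_dust(seq: str, offset: int, threshold: float, window: int) -> list[tuple[int, int]]:
    """Qualifying intervals within one N-free segment (O(n*window))."""
    n = len(seq)
    hits: list[tuple[int, int]] = []
    codes = [_TRIPLET_BASES[b] for b in seq]
    for end in range(4, n + 1):  # exclusive end of candidate interval
        counts: dict[int, int] = {}
        total = 0
        lo = max(0, end - window)
        # extend interval leftwards from end-3 (triplet start), accumulating
        t_starts = range(end - 3, lo - 1, -1)
        best: tuple[int, int] | None = None
        for s in t_starts:
            t = (codes[s] << 4) | (codes[s + 1] << 2) | codes[s + 2]
            c = counts.get(t, 0)
            total += c
            counts[t] = c + 1
            L = end - s
            if L >= 4 and 10.0 * total / (L - 3) >= threshold:
                best = (s, end)
        if best is not None:
            hits.append((best[0] + offset, best[1] + offset))
    return hits


def sdust_intervals(
    sequence: str,
    score_threshold: float = 28.0,
    window: int = 64,
    chrom: str = "1",
) -> list[GenomicInterval]:
    """Low-complexity intervals whose DUST score meets the threshold.

    For each end position only the widest qualifying interval is kept
    before merging; the merged result equals the union of every
    qualifying (length <= window) interval.
    """
    if window < 4:
        raise ValueError(f"window must be >= 4, got {window}")
    seq = sequence.upper()
    hits: list[tuple[int, int]] = []
    for m in re.finditer(r"[ACGT]+", seq):
        hits.extend(_segment_dust(m.group(0), m.start(), score_threshold, window))
    return normalize_intervals(GenomicInterval(chrom, s, e) for s, e in hits)


def homopolymer_intervals(
    sequence: str, min_len: int = 7, chrom: str = "1"
) -> list[GenomicInterval]:
    """Maximal single-nucleotide runs of length >= min_len (N runs ignored)."""
    seq = sequence.upper()
    out = []
    for m in re.finditer(r"([ACGT])\1*", seq):
        if m.end() - m.start() >= min_len:
            out.append(GenomicInterval(chrom, m.start(), m.end()))
    return out


@dataclass
class MaskTrack:
    """The merged low-complexity filter track with per-source provenance."""

    intervals: list[GenomicInterval]
    provenance: dict[str, list[GenomicInterval]] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.intervals)


def build_mask_track(
    dust: Iterable[GenomicInterval],
    homopolymers: Iterable[GenomicInterval],
    satellites: Iterable[GenomicInterval],
    chrom_lengths: Mapping[str, int],
    pad: int = 10,
) -> MaskTrack:
    """Union of the three sources, padded by ``pad`` bp each side, clipped
    to chromosome bounds and re-merged."""
    sources = {
        "dust": list(dust),
        "homopolymer": list(homopolymers),
        "satellite": list(satellites),
    }
    padded: list[GenomicInterval] = []
    for tag, track in sources.items():
        for iv in track:
            if iv.chrom not in chrom_lengths:
                raise ValueError(f"{tag} interval on unknown chromosome {iv.chrom!r}")
            start = max(0, iv.start - pad)
            end = min(chrom_lengths[iv.chrom], iv.end + pad)
            padded.append(GenomicInterval(iv.chrom, start, end))
    return MaskTrack(intervals=normalize_intervals(padded), provenance=sources)
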
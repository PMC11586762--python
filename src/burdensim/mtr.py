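"""Missense tolerance profiling along a coding sequence.

For every codon the nine single-base substitutions are classified from the
standard codon table; observed variants are binned per codon.  In a sliding
window of ``window`` codons (truncated at the edges) the ratio is

    MTR = (obs_mis / (obs_mis + obs_syn)) / (poss_mis / (poss_mis + poss_syn))

and is left undefined (NaN) where a window holds no observed variants.
Stop-gain substitutions count as neither missense nor synonymous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

__all__ = ["MTRTrack", "possible_substitution_counts", "compute_mtr"]

_BASES = "ACGT"
_FORWARD = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)


def _translate(codon: str) -> str | None:
    """Amino acid for a codon, None for stop."""
    return None if codon in _STOPS else _FORWARD[codon]


def possible_substitution_counts(codon: str) -> tuple[int, int]:
    """(missense, synonymous) counts over the codon's 9 substitutions."""
    aa = _translate(codon)
    if aa is None:
        raise ValueError(f"stop codon {codon} in frame")
    mis = syn = 0
    for i in range(3):
        for b in _BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1:]
            alt_aa = _translate(alt)
            if alt_aa is None:
                continue  # stop-gain: excluded from both classes
            if alt_aa == aa:
                syn += 1
            else:
                mis += 1
    return mis, syn


@dataclass
class MTRTrack:
    window_size: int
    codon_positions: np.ndarray  # 0-based codon index of each window center
    mtr: np.ndarray  # NaN where undefined
    obs_mis: np.ndarray
    obs_syn: np.ndarray
    poss_mis: np.ndarray
    poss_syn: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "codon": self.codon_positions,
                "mtr": self.mtr,
                "obs_mis": self.obs_mis,
                "obs_syn": self.obs_syn,
                "poss_mis": self.poss_mis,
                "poss_syn": self.poss_syn,
            }
        )


def _window_sums(values: np.ndarray, half: int) -> np.ndarray:
    """Centered sliding-window sums with truncated edges."""
    n = len(values)
    cum = np.concatenate([[0], np.cumsum(values)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return cum[hi] - cum[lo]


def compute_mtr(
    coding_sequence: str,
    observed: Iterable[tuple[int, str]] | Sequence[tuple[int, str]],
    window: int = 31,
) -> MTRTrack:
    """Missense tolerance track over a CDS.

    ``observed`` yields (codon_index, consequence) pairs with consequence in
    {"missense", "synonymous"}; other consequences are ignored.  The CDS
    must be a multiple of 3 with no in-frame stop codon.
    """
    seq = coding_sequence.upper()
    if len(seq) % 3 != 0:
        raise ValueError("coding sequence length must be divisible by 3")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd codon count")
    n_codons = len(seq) // 3
    poss_mis = np.zeros(n_codons)
    poss_syn = np.zeros(n_codons)
    for c in range(n_codons):
        codon = seq[3 * c: 3 * c + 3]
        poss_mis[c], poss_syn[c] = possible_substitution_counts(codon)
    obs_mis = np.zeros(n_codons)
    obs_syn = np.zeros(n_codons)
    for codon_idx, consequence in observed:
        if not (0 <= codon_idx < n_codons):
            raise ValueError(f"codon index {codon_idx} outside the CDS")
        if consequence == "missense":
            obs_mis[codon_idx] += 1
        elif consequence == "synonymous":
            obs_syn[codon_idx] += 1
    half = window // 2
    w_obs_mis = _window_sums(obs_mis, half)
    w_obs_syn = _window_sums(obs_syn, half)
    w_poss_mis = _window_sums(poss_mis, half)
    w_poss_syn = _window_sums(poss_syn, half)
    obs_total = w_obs_mis + w_obs_syn
    poss_total = w_poss_mis + w_poss_syn
    with np.errstate(divide="ignore", invalid="ignore"):
        obs_prop = np.where(obs_total > 0, w_obs_mis / obs_total, np.nan)
        poss_prop = np.where(poss_total > 0, w_poss_mis / poss_total, np.nan)
        mtr = obs_prop / poss_prop
    mtr[~np.isfinite(mtr) & (obs_total == 0)] = np.nan
    return MTRTrack(
        window_size=window,
        codon_positions=np.arange(n_codons),
        mtr=mtr,
        obs_mis=w_obs_mis,
        obs_syn=w_obs_syn,
        poss_mis=w_poss_mis,
        poss_syn=w_poss_syn,
    )
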
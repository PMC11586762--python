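"""LD pruning from co-occurrence counts (database side) and from dosage
correlation (cohort side).

Within a linked pair the variant with the larger AN (better called) is
retained; ties break toward the smaller packed key.  Database pruning is
applied per ancestry only, so other ancestries' summary statistics are
untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .keys import VariantKey
from .types import MISSING, AncestryLabel, CohortGenotypeMatrix, PopulationVariantStats

__all__ = [
    "LDPair",
    "r2_from_haplotype_counts",
    "read_cooccurrence_table",
    "flag_database_ld",
    "prune_cohort_ld",
]

DEFAULT_WINDOW = 10_000
DEFAULT_R2_DB = 0.95  # inclusive (>=) for the database round
DEFAULT_R2_COHORT = 0.95  # exclusive (>) for the cohort round


@dataclass(frozen=True)
class LDPair:
    key_a: VariantKey
    key_b: VariantKey
    r2: float
    ancestry: AncestryLabel | str  # AncestryLabel or "COHORT"


def r2_from_haplotype_counts(n_AB: int, n_Ab: int, n_aB: int, n_ab: int) -> float:
    """Squared correlation from the four joint haplotype counts.

    Capital letters denote the focal allele at each site, so the arguments
    count haplotypes carrying (both, first only, second only, neither).
    Monomorphic margins return 0 by convention.
    """
    n = n_AB + n_Ab + n_aB + n_ab
    if n < 1:
        raise ValueError("need at least one haplotype")
    p_ab = n_AB / n
    p_a = (n_AB + n_Ab) / n
    p_b = (n_AB + n_aB) / n
    va = p_a * (1 - p_a)
    vb = p_b * (1 - p_b)
    if va == 0 or vb == 0:
        return 0.0
    d = p_ab - p_a * p_b
    return (d * d) / (va * vb)


def read_cooccurrence_table(path: str | Path) -> pd.DataFrame:
    """Read a co-occurrence TSV: chrom_a,pos_a,ref_a,alt_a,chrom_b,pos_b,
    ref_b,alt_b,pop,n_AB,n_Ab,n_aB,n_ab (counts of joint haplotypes; capital
    letter = alt allele at that site)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom_a": str, "chrom_b": str,
                                            "ref_a": str, "alt_a": str,
                                            "ref_b": str, "alt_b": str})
    df["key_a"] = [VariantKey(r.chrom_a, int(r.pos_a), r.ref_a, r.alt_a)
                   for r in df.itertuples(index=False)]
    df["key_b"] = [VariantKey(r.chrom_b, int(r.pos_b), r.ref_b, r.alt_b)
                   for r in df.itertuples(index=False)]
    return df


def _greedy_prune(
    pairs: list[tuple[VariantKey, VariantKey]],
    rank: Mapping[VariantKey, float],
) -> set[VariantKey]:
    """Prune so no linked pair survives, keeping better-ranked variants.

    Candidates are visited best-first (higher rank, then smaller packed
    key); a visited variant not already pruned is retained and its linked
    partners pruned.  A fully linked clique of size k loses exactly k-1.
    """
    adj: dict[VariantKey, set[VariantKey]] = {}
    for a, b in pairs:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    order = sorted(adj, key=lambda k: (-rank.get(k, 0.0), k.packed))
    pruned: set[VariantKey] = set()
    for v in order:
        if v in pruned:
            continue
        pruned |= adj[v] - {v}
    return pruned


def flag_database_ld(
    cooccurrence: pd.DataFrame,
    db: Mapping[VariantKey, PopulationVariantStats] | None = None,
    window: int = DEFAULT_WINDOW,
    r2_min: float = DEFAULT_R2_DB,
) -> dict[AncestryLabel, set[VariantKey]]:
    """Per-ancestry prune sets from database co-occurrence counts.

    A pair participates when it is on one chromosome within ``window`` bp
    and r2 >= r2_min.  The returned sets are per ancestry; removing a
    variant for one ancestry leaves the others' statistics untouched.
    """
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    out: dict[AncestryLabel, set[VariantKey]] = {}
    for pop_value, sub in cooccurrence.groupby("pop"):
        pop = AncestryLabel(pop_value)
        linked: list[tuple[VariantKey, VariantKey]] = []
        for row in sub.itertuples(index=False):
            a, b = row.key_a, row.key_b
            if a.chrom != b.chrom or abs(a.pos - b.pos) > window:
                continue
            r2 = r2_from_haplotype_counts(row.n_AB, row.n_Ab, row.n_aB, row.n_ab)
            if r2 >= r2_min:
                linked.append((a, b))
        rank = {}
        if db is not None:
            for a, b in linked:
                for k in (a, b):
                    if k in db:
                        rank[k] = float(db[k].an.get(pop, 0))
        out[pop] = _greedy_prune(linked, rank)
    return out


def prune_cohort_ld(
    cohort: CohortGenotypeMatrix,
    qualifying: Iterable[VariantKey] | None = None,
    window: int = DEFAULT_WINDOW,
    r2_min: float = DEFAULT_R2_COHORT,
) -> set[VariantKey]:
    """Cohort-level pruning via squared Pearson correlation of dosages.

    Pairs with fewer than two jointly non-missing samples, or with a
    monomorphic dosage column, are skipped.  The threshold is exclusive
    (r2 strictly greater prunes).
    """
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    keys = list(qualifying) if qualifying is not None else list(cohort.variants)
    keys = [k for k in keys if k in cohort._index]
    keys.sort(key=lambda k: k.packed)
    linked: list[tuple[VariantKey, VariantKey]] = []
    n_called: dict[VariantKey, float] = {}
    for i, a in enumerate(keys):
        ra = cohort.dosage[cohort.variant_index(a)]
        n_called[a] = float((ra != MISSING).sum())
        for b in keys[i + 1:]:
            if b.chrom != a.chrom or b.pos - a.pos > window:
                break
            rb = cohort.dosage[cohort.variant_index(b)]
            joint = (ra != MISSING) & (rb != MISSING)
            if joint.sum() < 2:
                continue
            xa = ra[joint].astype(float)
            xb = rb[joint].astype(float)
            if xa.std() == 0 or xb.std() == 0:
                continue
            r = np.corrcoef(xa, xb)[0, 1]
            if r * r > r2_min:
                linked.append((a, b))
    return _greedy_prune(linked, n_called)
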
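"""Reciprocal variant filtering: population-derived filters, cohort-derived
site filters, qualifying-variant selection, and harmonization.

A variant excluded in either the cohort or the control database is excluded
in both.  HWE and excess-heterozygosity are soft flags (annotations); the
rest are hard filters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .intervals import IntervalIndex
from .keys import VariantKey
from .mask import MaskTrack
from .types import (
    MISSING,
    AncestryLabel,
    CohortGenotypeMatrix,
    CONTINENTAL_ANCESTRIES,
    PopulationVariantStats,
    VariantAnnotation,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FilterFlagSet",
    "HARD_FLAGS",
    "SOFT_FLAGS",
    "apply_population_filters",
    "site_quality_filters",
    "hwe_exact_p",
    "excess_het_phred",
    "ac0_flag",
    "select_qualifying_variants",
    "reciprocal_harmonize",
]

HARD_FLAGS = frozenset(
    {"db_qc_fail", "gnomadDP0", "ns5000", "lcr", "sor", "missing", "AC0",
     "ld_eur", "ld_afr", "ld_amr", "ld_sas", "ld_eas", "ld_cohort"}
)
SOFT_FLAGS = frozenset({"hwe", "excesshet"})

MIN_CALLED_INDIVIDUALS = 5_000
SOR_MAX = 3.0
EXCESS_HET_MAX = 100.0
HWE_P_MIN = 0.001
MISSING_FRACTION_MAX = 0.01


@dataclass
class FilterFlagSet:
    """Named per-variant flags; hard flags exclude, soft flags annotate."""

    flags: dict[str, set[VariantKey]] = field(default_factory=dict)

    def add(self, name: str, key: VariantKey) -> None:
        if name not in HARD_FLAGS and name not in SOFT_FLAGS:
            raise ValueError(f"unknown filter flag {name!r}")
        self.flags.setdefault(name, set()).add(key)

    def variants_with(self, name: str) -> set[VariantKey]:
        return self.flags.get(name, set())

    def hard_excluded(self) -> set[VariantKey]:
        out: set[VariantKey] = set()
        for name, keys in self.flags.items():
            if name in HARD_FLAGS:
                out |= keys
        return out

    def soft_annotations(self) -> dict[VariantKey, set[str]]:
        out: dict[VariantKey, set[str]] = {}
        for name, keys in self.flags.items():
            if name in SOFT_FLAGS:
                for k in keys:
                    out.setdefault(k, set()).add(name)
        return out

    def merged_with(self, other: "FilterFlagSet") -> "FilterFlagSet":
        merged = FilterFlagSet()
        for src in (self, other):
            for name, keys in src.flags.items():
                merged.flags.setdefault(name, set()).update(keys)
        return merged


def apply_population_filters(
    db: Mapping[VariantKey, PopulationVariantStats],
    calling_regions: IntervalIndex | None = None,
    min_called: int = MIN_CALLED_INDIVIDUALS,
) -> FilterFlagSet:
    """Database-side filters: QC failures, uncovered regions, low call rate.

    ``calling_regions`` indexes the documented calling intervals; a variant
    whose position falls outside them (or whose record carries
    covered=False) receives the coverage flag.  Records lacking an explicit
    call count fall back to AN/2 over the available ancestries.
    """
    flags = FilterFlagSet()
    for key, rec in db.items():
        if not rec.qc_pass:
            flags.add("db_qc_fail", key)
        covered = rec.covered
        if calling_regions is not None:
            covered = covered and calling_regions.contains(key.chrom, key.pos - 1)
        if not covered:
            flags.add("gnomadDP0", key)
        n_called = rec.n_called_individuals
        if not n_called:
            n_called = sum(rec.an.values()) // 2
        if n_called < min_called:
            flags.add("ns5000", key)
    return flags


def _hwe_het_probabilities(n: int, n_alt: int) -> np.ndarray:
    """P(het = h | allele count) for all h with the parity of n_alt."""
    h_min = n_alt % 2
    h_max = min(n_alt, 2 * n - n_alt)
    hs = list(range(h_min, h_max + 1, 2))
    logp = []
    for h in hs:
        n_aa = (n_alt - h) // 2
        n_rr = n - n_aa - h
        logp.append(
            math.lgamma(n + 1)
            - math.lgamma(n_rr + 1) - math.lgamma(h + 1) - math.lgamma(n_aa + 1)
            + h * math.log(2)
        )
    p = np.exp(np.array(logp) - max(logp))
    return p / p.sum()


def hwe_exact_p(hom_ref: int, het: int, hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test.

    Sums, over all heterozygote configurations compatible with the observed
    allele counts, the probabilities no larger than that of the observed
    configuration.
    """
    if min(hom_ref, het, hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = hom_ref + het + hom_alt
    if n < 1:
        raise ValueError("need at least one genotype")
    n_alt = 2 * hom_alt + het
    if n_alt == 0 or n_alt == 2 * n:
        return 1.0
    probs = _hwe_het_probabilities(n, n_alt)
    h_min = n_alt % 2
    obs_idx = (het - h_min) // 2
    p_obs = probs[obs_idx]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def excess_het_phred(hom_ref: int, het: int, hom_alt: int) -> float:
    """Phred-scaled one-sided exact-test p for heterozygote excess."""
    n = hom_ref + het + hom_alt
    n_alt = 2 * hom_alt + het
    if n < 1 or n_alt == 0 or n_alt == 2 * n:
        return 0.0
    probs = _hwe_het_probabilities(n, n_alt)
    h_min = n_alt % 2
    obs_idx = (het - h_min) // 2
    p = float(probs[obs_idx:].sum())
    return -10.0 * math.log10(max(p, 1e-300))


def site_quality_filters(
    cohort: CohortGenotypeMatrix,
    sor_max: float = SOR_MAX,
    excess_het_max: float = EXCESS_HET_MAX,
    hwe_p_min: float = HWE_P_MIN,
    missing_max: float = MISSING_FRACTION_MAX,
) -> FilterFlagSet:
    """Cohort-side site filters: strand bias, het excess, HWE, missingness.

    When SOR is absent from the input it is skipped with a warning rather
    than guessed; absent ExcessHet is recomputed from genotype counts.
    """
    flags = FilterFlagSet()
    miss = cohort.missing_fraction
    sor_missing = 0
    for i, key in enumerate(cohort.variants):
        if np.isfinite(cohort.sor[i]):
            if cohort.sor[i] > sor_max:
                flags.add("sor", key)
        else:
            sor_missing += 1
        hr, het, ha = cohort.genotype_counts(i)
        eh = cohort.excess_het[i]
        if not np.isfinite(eh):
            eh = excess_het_phred(hr, het, ha) if (hr + het + ha) else 0.0
        if eh > excess_het_max:
            flags.add("excesshet", key)
        if (hr + het + ha) >= 1 and hwe_exact_p(hr, het, ha) < hwe_p_min:
            flags.add("hwe", key)
        if miss[i] > missing_max:
            flags.add("missing", key)
    if sor_missing:
        logger.warning(
            "SOR unavailable for %d variants; strand-bias filter skipped there",
            sor_missing,
        )
    return flags


def ac0_flag(
    cohort: CohortGenotypeMatrix,
    ab_lo: float = 0.2,
    ab_hi: float = 0.8,
    dp_min: int = 10,
    gq_min: int = 20,
) -> FilterFlagSet:
    """Flag sites where every carrier fails the confidence criteria.

    A carrier passes when its allele balance lies in [ab_lo, ab_hi] (the AB
    check only applies to heterozygous calls, where AB is defined) and it is
    not simultaneously low-depth and low-quality.  Sites with no carriers
    are never flagged.
    """
    flags = FilterFlagSet()
    for i, key in enumerate(cohort.variants):
        carriers = np.where(cohort.dosage[i] > 0)[0]
        if carriers.size == 0:
            continue
        any_pass = False
        for j in carriers:
            ab = cohort.ab[i, j]
            ab_ok = (not np.isfinite(ab)) or (ab_lo <= ab <= ab_hi)
            dp, gq = cohort.dp[i, j], cohort.gq[i, j]
            low_quality = (dp != MISSING and dp < dp_min) and (gq != MISSING and gq < gq_min)
            if ab_ok and not low_quality:
                any_pass = True
                break
        if not any_pass:
            flags.add("AC0", key)
    return flags


def select_qualifying_variants(
    annotations: Mapping[VariantKey, VariantAnnotation],
    db: Mapping[VariantKey, PopulationVariantStats] | None = None,
    af_max: float = 0.01,
    cadd_min: float = 20.0,
    consequence_set: Iterable[str] = ("pLOF", "missense", "inframe_indel"),
    tested_ancestries: Iterable[AncestryLabel] = CONTINENTAL_ANCESTRIES,
) -> set[VariantKey]:
    """Rarity / deleteriousness / consequence selection.

    The allele frequency must be below ``af_max`` in every tested ancestry
    (taken from the annotation, falling back to AC/AN from the database).
    With cadd_min > 0, variants lacking a CADD score are excluded; at
    cadd_min == 0 any annotated variant qualifies regardless of score,
    which is how the domain-level analysis is configured.
    """
    consequence_set = set(consequence_set)
    tested = list(tested_ancestries)
    out: set[VariantKey] = set()
    for key, ann in annotations.items():
        if ann.consequence not in consequence_set:
            continue
        if cadd_min > 0 and (ann.cadd_phred is None or ann.cadd_phred < cadd_min):
            continue
        rare = True
        for pop in tested:
            af = ann.af_pop.get(pop)
            if af is None and db is not None and key in db:
                af = db[key].af(pop)
            if af is not None and af >= af_max:
                rare = False
                break
        if rare:
            out.add(key)
    return out


def reciprocal_harmonize(
    cohort_flags: FilterFlagSet,
    db_flags: FilterFlagSet,
    lcr: MaskTrack | None = None,
    variants: Iterable[VariantKey] = (),
) -> tuple[set[VariantKey], dict[VariantKey, set[str]]]:
    """Unified exclusion set plus soft-flag annotations.

    Hard exclusion is the union of hard flags from either side plus
    low-complexity membership (a variant is masked when its reference-allele
    span intersects the track).  Soft flags are returned as annotations.
    """
    merged = cohort_flags.merged_with(db_flags)
    excluded = merged.hard_excluded()
    if lcr is not None:
        index = IntervalIndex(lcr.intervals)
        for key in variants:
            if index.overlaps(key.chrom, key.pos - 1, key.pos - 1 + len(key.ref)):
                merged.add("lcr", key)
                excluded.add(key)
    return excluded, merged.soft_annotations()
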
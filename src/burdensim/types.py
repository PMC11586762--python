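"""Domain types shared across the framework."""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .keys import VariantKey

__all__ = [
    "AncestryLabel",
    "CONTINENTAL_ANCESTRIES",
    "PopulationVariantStats",
    "CohortGenotypeMatrix",
    "VariantAnnotation",
    "AggregationUnit",
]

MISSING = -1  # sentinel for absent integer genotype data


class AncestryLabel(str, enum.Enum):
    EUR = "EUR"
    AFR = "AFR"
    AMR = "AMR"
    SAS = "SAS"
    EAS = "EAS"
    UNKNOWN = "UNKNOWN"

    def __str__(self) -> str:
        return self.value


#: the five groups eligible for burden testing; UNKNOWN is always excluded
CONTINENTAL_ANCESTRIES = (
    AncestryLabel.EUR,
    AncestryLabel.AFR,
    AncestryLabel.AMR,
    AncestryLabel.SAS,
    AncestryLabel.EAS,
)


@dataclass
class PopulationVariantStats:
    """Per-variant, per-ancestry allele counts from the control database."""

    key: VariantKey
    ac: dict[AncestryLabel, int] = field(default_factory=dict)
    an: dict[AncestryLabel, int] = field(default_factory=dict)
    hom_alt: dict[AncestryLabel, int] = field(default_factory=dict)
    qc_pass: bool = True
    covered: bool = True
    n_called_individuals: int = 0

    def validate(self) -> None:
        for pop, ac in self.ac.items():
            an = self.an.get(pop, 0)
            if ac < 0 or an < 0:
                raise ValueError(f"negative counts for {self.key} {pop}")
            if ac > an:
                raise ValueError(f"AC > AN for variant {self.key} in {pop}: {ac} > {an}")
            hom = self.hom_alt.get(pop, 0)
            if 2 * hom > ac:
                raise ValueError(f"2*hom_alt > AC for variant {self.key} in {pop}")

    def af(self, pop: AncestryLabel) -> float:
        an = self.an.get(pop, 0)
        return self.ac.get(pop, 0) / an if an else 0.0


@dataclass
class VariantAnnotation:
    key: VariantKey
    gene_id: str
    consequence: str  # pLOF | missense | inframe_indel | synonymous | other
    cadd_phred: float | None = None
    af_pop: dict[AncestryLabel, float] = field(default_factory=dict)
    domain_id: str | None = None


@dataclass
class AggregationUnit:
    """A set of variants tested together (gene, domain, pathway, custom)."""

    unit_id: str
    level: str
    member_keys: frozenset[VariantKey]

    def __post_init__(self) -> None:
        if self.level not in ("gene", "domain", "pathway", "custom"):
            raise ValueError(f"unknown aggregation level {self.level!r}")
        self.member_keys = frozenset(self.member_keys)


class CohortGenotypeMatrix:
    """samples x variants dosage matrix with per-genotype quality fields.

    Arrays are (n_variants, n_samples); dosage/DP/GQ use -1 for missing and
    AB uses NaN.  Site metrics (SOR, ExcessHet) are NaN when unavailable.
    """

    def __init__(
        self,
        samples: Sequence[str],
        ancestry: Mapping[str, AncestryLabel],
        variants: Sequence[VariantKey],
        dosage: np.ndarray,
        dp: np.ndarray | None = None,
        gq: np.ndarray | None = None,
        ab: np.ndarray | None = None,
        sor: np.ndarray | None = None,
        excess_het: np.ndarray | None = None,
    ):
        self.samples = list(samples)
        self.ancestry = {
            s: ancestry.get(s, AncestryLabel.UNKNOWN) for s in self.samples
        }
        self.variants = list(variants)
        n_var, n_smp = len(self.variants), len(self.samples)
        shape = (n_var, n_smp)
        self.dosage = np.asarray(dosage, dtype=np.int8)
        if self.dosage.shape != shape:
            raise ValueError(f"dosage shape {self.dosage.shape} != {shape}")
        self.dp = np.full(shape, MISSING, dtype=np.int32) if dp is None else np.asarray(dp, dtype=np.int32)
        self.gq = np.full(shape, MISSING, dtype=np.int32) if gq is None else np.asarray(gq, dtype=np.int32)
        self.ab = np.full(shape, np.nan) if ab is None else np.asarray(ab, dtype=float)
        self.sor = np.full(n_var, np.nan) if sor is None else np.asarray(sor, dtype=float)
        self.excess_het = np.full(n_var, np.nan) if excess_het is None else np.asarray(excess_het, dtype=float)
        self._index = {k: i for i, k in enumerate(self.variants)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, key: VariantKey) -> int:
        return self._index[key]

    @property
    def missing_fraction(self) -> np.ndarray:
        return (self.dosage == MISSING).mean(axis=1)

    def allele_counts(self) -> np.ndarray:
        """Per-variant alternate allele count over non-missing genotypes."""
        d = self.dosage.astype(np.int64)
        return np.where(d == MISSING, 0, d).sum(axis=1)

    def genotype_counts(self, i: int) -> tuple[int, int, int]:
        """(hom_ref, het, hom_alt) at variant index i, ignoring missing."""
        row = self.dosage[i]
        return int((row == 0).sum()), int((row == 1).sum()), int((row == 2).sum())

    def sample_indices(self, label: AncestryLabel) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.samples) if self.ancestry[s] == label],
            dtype=int,
        )

    def ancestry_sizes(self) -> dict[AncestryLabel, int]:
        sizes: dict[AncestryLabel, int] = {}
        for s in self.samples:
            lbl = self.ancestry[s]
            sizes[lbl] = sizes.get(lbl, 0) + 1
        return sizes
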
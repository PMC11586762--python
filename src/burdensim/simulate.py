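"""Synthetic inputs: population database, annotations, cohorts with an
optional spiked gene, ancestry fixtures, and sequences with planted
low-complexity features.  Everything is deterministic under the seed and
ships with a truth manifest so tests never reach into generator internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .keys import VariantKey
from .intervals import GenomicInterval
from .types import (
    MISSING,
    AncestryLabel,
    CohortGenotypeMatrix,
    PopulationVariantStats,
    VariantAnnotation,
)

__all__ = [
    "SimulationConfig",
    "generate_population_db",
    "generate_cohort",
    "generate_sequences",
    "generate_ancestry_fixture",
]

_DEFAULT_SIZES = {
    AncestryLabel.EUR: 40,
    AncestryLabel.AFR: 40,
    AncestryLabel.AMR: 40,
    AncestryLabel.SAS: 40,
}

_CONSEQUENCES = ("missense", "pLOF", "inframe_indel", "synonymous", "other")


@dataclass
class SpikeConfig:
    gene_id: str
    target_or: float
    ancestry_weights: dict[AncestryLabel, float] | None = None


@dataclass
class SimulationConfig:
    seed: int = 0
    ancestry_sizes: dict[AncestryLabel, int] = field(
        default_factory=lambda: dict(_DEFAULT_SIZES)
    )
    an_per_ancestry: int = 20_000
    n_genes: int = 100
    variants_per_gene: int = 6
    af_range: tuple[float, float] = (1e-5, 5e-3)
    af_ancestry_jitter_sd: float = 0.3  # lognormal sd on the per-pop AF
    cadd_high_fraction: float = 0.6
    consequence_probs: tuple[float, ...] = (0.70, 0.10, 0.05, 0.10, 0.05)
    variant_spacing: int = 20_001  # > LD window so null genes never self-prune
    spike: SpikeConfig | None = None
    missing_rate: float = 0.0
    per_variant_missing: dict[VariantKey, float] | None = None
    ab_noise_sd: float = 0.03
    low_quality_fraction: float = 0.0

    def __post_init__(self) -> None:
        for rate in (self.missing_rate, self.cadd_high_fraction, self.low_quality_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if any(n <= 0 for n in self.ancestry_sizes.values()):
            raise ValueError("ancestry sizes must be positive")


def _gene_ids(n: int) -> list[str]:
    return [f"GENE{i:05d}" for i in range(n)]


def generate_population_db(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[VariantKey, PopulationVariantStats], dict[VariantKey, VariantAnnotation]]:
    """Synthetic control database plus a matching annotation table.

    Per-ancestry AC are binomial draws around a shared log-uniform base
    frequency; annotation AFs are AC/AN exactly, so the AF-consistency
    invariant holds by construction.
    """
    rng = rng or np.random.default_rng(config.seed)
    pops = list(config.ancestry_sizes)
    db: dict[VariantKey, PopulationVariantStats] = {}
    annotations: dict[VariantKey, VariantAnnotation] = {}
    lo, hi = config.af_range
    alts = {"A": "G", "C": "T", "G": "A", "T": "C"}
    for g, gene in enumerate(_gene_ids(config.n_genes)):
        chrom = str((g % 22) + 1)
        gene_start = 1_000_000 + (g // 22) * (config.variants_per_gene + 2) * config.variant_spacing
        for v in range(config.variants_per_gene):
            pos = gene_start + v * config.variant_spacing
            ref = "ACGT"[(g + v) % 4]
            key = VariantKey(chrom, pos, ref, alts[ref])
            base_af = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            rec = PopulationVariantStats(key=key, qc_pass=True, covered=True)
            af_pop: dict[AncestryLabel, float] = {}
            for pop in pops:
                af = min(0.5, base_af * float(rng.lognormal(0.0, config.af_ancestry_jitter_sd)))
                an = config.an_per_ancestry
                ac = int(rng.binomial(an, af))
                rec.ac[pop] = ac
                rec.an[pop] = an
                rec.hom_alt[pop] = 0
                af_pop[pop] = ac / an
            rec.n_called_individuals = sum(rec.an.values()) // 2
            db[key] = rec
            high = rng.random() < config.cadd_high_fraction
            cadd = float(rng.uniform(20.0, 40.0)) if high else float(rng.uniform(0.01, 19.99))
            consequence = str(rng.choice(_CONSEQUENCES, p=config.consequence_probs))
            if config.spike is not None and gene == config.spike.gene_id:
                # the spiked gene's variants must survive qualification
                consequence = "missense"
                cadd = float(rng.uniform(25.0, 40.0))
            annotations[key] = VariantAnnotation(
                key=key, gene_id=gene, consequence=consequence,
                cadd_phred=cadd, af_pop=af_pop, domain_id=None,
            )
    return db, annotations


def _spike_lambda(afs: np.ndarray, target_p: float) -> float:
    """Scale factor on per-variant AFs achieving carrier probability target_p.

    Scaled AFs cap at 0.5 per variant (beyond that the unit is no longer a
    rare-variant burden), which bounds the attainable carrier probability.
    """

    def carrier_p(lam: float) -> float:
        return 1.0 - float(np.prod((1.0 - np.minimum(lam * afs, 0.5)) ** 2))

    p_max = carrier_p(1e9)
    if target_p > p_max:
        raise ValueError(
            f"target carrier probability {target_p:.4g} unreachable; "
            f"attainable bound is {p_max:.4g} at the given AFs"
        )
    lo_l, hi_l = 1.0, 1.0
    while carrier_p(hi_l) < target_p:
        hi_l *= 2.0
    for _ in range(80):
        mid = 0.5 * (lo_l + hi_l)
        if carrier_p(mid) < target_p:
            lo_l = mid
        else:
            hi_l = mid
    return 0.5 * (lo_l + hi_l)


def generate_cohort(
    db: Mapping[VariantKey, PopulationVariantStats],
    annotations: Mapping[VariantKey, VariantAnnotation],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[CohortGenotypeMatrix, dict]:
    """Draw a cohort from the database under the engine's null, optionally
    inflating one gene's carrier probability to a target odds ratio.

    Null genotypes per ancestry come from hypergeometric allele sampling
    (2N draws from the AN database alleles) with alleles assigned to sample
    slots uniformly, exactly matching the simulation model.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    samples: list[str] = []
    ancestry: dict[str, AncestryLabel] = {}
    group_cols: dict[AncestryLabel, np.ndarray] = {}
    for pop, n in config.ancestry_sizes.items():
        start = len(samples)
        for i in range(n):
            sid = f"{pop.value}_{i:04d}"
            samples.append(sid)
            ancestry[sid] = pop
        group_cols[pop] = np.arange(start, start + n)
    n_samples = len(samples)

    keys = sorted(db, key=lambda k: k.packed)
    spike_keys: set[VariantKey] = set()
    spike_lam: dict[AncestryLabel, float] = {}
    truth: dict = {"ancestry_sizes": {p.value: n for p, n in config.ancestry_sizes.items()}}
    if config.spike is not None:
        spike_keys = {
            k for k in keys if annotations[k].gene_id == config.spike.gene_id
        }
        if not spike_keys:
            raise ValueError(f"spike gene {config.spike.gene_id} not in the database")
        weights = config.spike.ancestry_weights or {p: 1.0 for p in config.ancestry_sizes}
        for pop in config.ancestry_sizes:
            afs = np.array([db[k].af(pop) for k in sorted(spike_keys, key=lambda k: k.packed)])
            p0 = 1.0 - float(np.prod((1.0 - afs) ** 2))
            w = weights.get(pop, 0.0)
            target_or = 1.0 + (config.spike.target_or - 1.0) * w
            odds = target_or * p0 / (1.0 - p0) if p0 < 1 else np.inf
            p1 = odds / (1.0 + odds)
            spike_lam[pop] = _spike_lambda(afs, p1) if p1 > p0 else 1.0
        truth["spiked_gene"] = config.spike.gene_id
        truth["true_or"] = config.spike.target_or

    dosage = np.zeros((len(keys), n_samples), dtype=np.int8)
    for i, key in enumerate(keys):
        rec = db[key]
        for pop, cols in group_cols.items():
            n = cols.size
            if key in spike_keys:
                af = min(0.5, spike_lam[pop] * rec.af(pop))
                g = rng.binomial(2, af, size=n).astype(np.int8)
                dosage[i, cols] = g
                continue
            an = rec.an.get(pop, 0)
            ac = rec.ac.get(pop, 0)
            if an < 2 * n:
                raise ValueError(f"AN={an} too small for {n} samples in {pop}")
            k_alt = int(rng.hypergeometric(ac, an - ac, 2 * n)) if ac else 0
            if k_alt:
                slots = rng.choice(2 * n, size=k_alt, replace=False)
                idx, per = np.unique(slots // 2, return_counts=True)
                dosage[i, cols[idx]] = per.astype(np.int8)

    # genotype-quality scaffolding and noise
    dp = rng.poisson(50, size=dosage.shape).astype(np.int32).clip(min=1)
    gq = np.full(dosage.shape, 99, dtype=np.int32)
    if config.low_quality_fraction > 0:
        lowq = rng.random(dosage.shape) < config.low_quality_fraction
        dp[lowq] = rng.integers(1, 10, size=int(lowq.sum()))
        gq[lowq] = rng.integers(0, 20, size=int(lowq.sum()))
    ab = np.full(dosage.shape, np.nan)
    hets = dosage == 1
    ab[hets] = np.clip(rng.normal(0.5, config.ab_noise_sd, size=int(hets.sum())), 0.05, 0.95)
    missing = rng.random(dosage.shape) < config.missing_rate
    if config.per_variant_missing:
        for key, rate in config.per_variant_missing.items():
            i = keys.index(key)
            missing[i] |= rng.random(n_samples) < rate
    dosage[missing] = MISSING
    dp[missing] = MISSING
    gq[missing] = MISSING
    ab[missing] = np.nan

    cohort = CohortGenotypeMatrix(
        samples=samples,
        ancestry=ancestry,
        variants=keys,
        dosage=dosage,
        dp=dp,
        gq=gq,
        ab=ab,
        sor=np.ones(len(keys)),
        excess_het=np.full(len(keys), np.nan),
    )
    if config.spike is not None:
        carrier_cols = np.where(
            (np.where(dosage == MISSING, 0, dosage)[
                [keys.index(k) for k in sorted(spike_keys, key=lambda k: k.packed)]
            ] > 0).any(axis=0)
        )[0]
        truth["spike_carriers"] = [samples[c] for c in carrier_cols]
    return cohort, truth


def generate_sequences(
    rng: np.random.Generator | None = None,
    neutral_len: int = 2_000,
    seed: int | None = 0,
    plant_features: bool = True,
) -> tuple[str, list[tuple[GenomicInterval, str]]]:
    """A synthetic chromosome with planted low-complexity features.

    The neutral background never repeats a base within distance two, which
    keeps it clear of homopolymer and DUST masks.  Returns the sequence and
    a truth list of (interval, feature-tag) pairs.
    """
    rng = rng or np.random.default_rng(seed)
    bases = "ACGT"

    def neutral(n: int, prefix: str = "") -> str:
        out = list(prefix)
        while len(out) - len(prefix) < n:
            choices = [b for b in bases if b not in out[-2:]]
            out.append(bases[int(rng.integers(4))] if not choices else choices[int(rng.integers(len(choices)))])
        return "".join(out[len(prefix):])

    parts: list[str] = []
    truth: list[tuple[GenomicInterval, str]] = []

    def append_neutral(n: int) -> None:
        parts.append(neutral(n, prefix="".join(parts)[-2:]))

    def plant(feature: str, tag: str) -> None:
        # keep the boundary clean: the neutral flank must not extend the run
        if parts and parts[-1] and parts[-1][-1] in feature[:2]:
            prev = parts[-1]
            banned = set(feature[:2])
            candidates = [b for b in bases if b not in banned and b != prev[-2:-1]]
            repl = candidates[0] if candidates else next(b for b in bases if b not in banned)
            parts[-1] = prev[:-1] + repl
        start = sum(len(p) for p in parts)
        parts.append(feature)
        truth.append((GenomicInterval("1", start, start + len(feature)), tag))

    append_neutral(neutral_len // 4)
    if plant_features:
        plant("A" * 12, "homopolymer")
    append_neutral(neutral_len // 4)
    if plant_features:
        plant("AT" * 20, "dinucleotide")
    append_neutral(neutral_len // 4)
    if plant_features:
        plant("T" * 8, "homopolymer")
    append_neutral(neutral_len // 4)
    return "".join(parts), truth


def generate_ancestry_fixture(
    n_per_group: int = 60,
    n_components: int = 4,
    separation: float = 10.0,
    seed: int = 0,
    groups: tuple[AncestryLabel, ...] = (AncestryLabel.EUR, AncestryLabel.AFR),
) -> tuple[pd.DataFrame, dict[str, AncestryLabel]]:
    """Labelled reference PC coordinates: one Gaussian cluster per group."""
    rng = np.random.default_rng(seed)
    rows = []
    labels: dict[str, AncestryLabel] = {}
    for gi, pop in enumerate(groups):
        center = np.zeros(n_components)
        center[gi % n_components] = separation * (1 + gi // n_components)
        for i in range(n_per_group):
            sid = f"ref_{pop.value}_{i:03d}"
            coords = center + rng.normal(0, 1.0, size=n_components)
            rows.append({"sample": sid, **{f"pc_{k+1}": coords[k] for k in range(n_components)}})
            labels[sid] = pop
    return pd.DataFrame(rows).set_index("sample"), labels
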
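"""Monte-Carlo burden engine.

For each qualifying variant and ancestry, a control cohort of N individuals
corresponds to 2N allele draws without replacement from the AN database
alleles, AC of which are alternate; the simulated unit burden is the sum of
per-variant hypergeometric variates, variants treated as independent after
LD pruning.  Empirical p-values use the add-one estimator
(r + 1) / (iterations + 1) so they are never zero; a burden never reached
in simulation is displayed as "< 1/iterations".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .keys import VariantKey
from .intervals import GenomicInterval, IntervalIndex
from .types import (
    MISSING,
    AncestryLabel,
    AggregationUnit,
    CohortGenotypeMatrix,
    CONTINENTAL_ANCESTRIES,
    PopulationVariantStats,
    VariantAnnotation,
)
from . import filters as _filters
from . import ld as _ld

logger = logging.getLogger(__name__)

__all__ = [
    "BurdenConfig",
    "BurdenDistribution",
    "BurdenResult",
    "observed_burden",
    "simulate_burden_distribution",
    "exact_burden_distribution",
    "empirical_pvalue",
    "format_pvalue",
    "combine_ancestries",
    "run_gene_burden",
    "run_domain_burden",
]

# inverse-CDF sampling is used while the variant's support stays this small;
# beyond it we defer to numpy's rejection sampler
_MAX_INVERSION_SUPPORT = 4096


@dataclass
class BurdenConfig:
    af_max: float = 0.01
    cadd_min: float = 20.0
    consequence_set: tuple[str, ...] = ("pLOF", "missense", "inframe_indel")
    iterations: int = 1_000_000
    seed: int = 0
    min_group_size: int = 10
    exome_wide_alpha: float = 2.5e-6
    af5_cohort_af: float = 0.05
    af5_db_af: float = 0.01
    burden_scale: str = "alleles"  # or "carriers"
    randomized_p: bool = False  # also report a PIT-randomized combined p (calibration only)
    ld_window: int = 10_000
    db_r2_min: float = 0.95
    cohort_r2_min: float = 0.95
    domain_shortlist_p: float = 0.001


@dataclass
class BurdenDistribution:
    """Empirical distribution of simulated aggregate burden for one unit."""

    unit_id: str
    ancestry: AncestryLabel
    iterations: int
    counts: np.ndarray  # histogram over X = 0, 1, 2, ...
    seed: int | None = None
    draws: np.ndarray | None = None  # per-iteration totals, kept on request

    def __post_init__(self) -> None:
        if int(self.counts.sum()) != self.iterations:
            raise ValueError("histogram mass does not match iteration count")

    def tail_count(self, b: int) -> int:
        if b <= 0:
            return self.iterations
        if b >= len(self.counts):
            return 0
        return int(self.counts[b:].sum())


@dataclass
class BurdenResult:
    unit_id: str
    b_pop: dict[AncestryLabel, int]
    p_pop: dict[AncestryLabel, float]
    combined_p: float | None
    combined_p_randomized: float | None = None
    flags: set[str] = field(default_factory=set)
    soft_filter_notes: dict[str, set[str]] = field(default_factory=dict)
    n_variants_observed: int = 0
    n_variants_expected_mean: float = 0.0
    b_total: int = 0
    display_p: str = ""
    exome_wide_significant: bool = False


def _unit_variant_stats(
    db: Mapping[VariantKey, PopulationVariantStats],
    members: Iterable[VariantKey],
    ancestry: AncestryLabel,
) -> list[tuple[int, int]]:
    """(AC, AN) per member for one ancestry, skipping uncalled variants."""
    out = []
    for key in sorted(members, key=lambda k: k.packed):
        rec = db.get(key)
        if rec is None:
            continue
        an = rec.an.get(ancestry, 0)
        if an <= 0:
            continue
        out.append((rec.ac.get(ancestry, 0), an))
    return out


def _sample_hypergeom(
    rng: np.random.Generator, ac: int, an: int, draws: int, size: int
) -> np.ndarray:
    """Hypergeometric variates; inverse-CDF sampling for small supports."""
    if ac == 0:
        return np.zeros(size, dtype=np.int64)
    support = min(ac, draws)
    if support <= _MAX_INVERSION_SUPPORT:
        k = np.arange(support + 1)
        cdf = np.cumsum(stats.hypergeom.pmf(k, an, ac, draws))
        cdf[-1] = 1.0
        return np.searchsorted(cdf, rng.random(size), side="right").astype(np.int64)
    return rng.hypergeometric(ac, an - ac, draws, size=size).astype(np.int64)


def simulate_burden_distribution(
    db: Mapping[VariantKey, PopulationVariantStats],
    unit: AggregationUnit,
    ancestry: AncestryLabel,
    n_pop: int,
    iterations: int = 1_000_000,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
    keep_draws: bool = False,
    allele_draws: int | None = None,
) -> BurdenDistribution:
    """Simulate the unit's aggregate control burden for one ancestry.

    Each iteration draws, per variant, the alternate alleles captured in
    2*n_pop allele draws from the AN database alleles, and records the sum.
    ``allele_draws`` overrides the 2*n_pop draw count (oracle comparisons).
    """
    if not unit.member_keys:
        raise ValueError(f"unit {unit.unit_id} has no member variants")
    pairs = _unit_variant_stats(db, unit.member_keys, ancestry)
    draws = 2 * n_pop if allele_draws is None else allele_draws
    for ac, an in pairs:
        if an < draws:
            raise ValueError(
                f"AN={an} in {ancestry} is smaller than the simulated cohort's "
                f"{draws} alleles for unit {unit.unit_id}"
            )
    if rng is None:
        rng = np.random.default_rng(seed)
    totals = np.zeros(iterations, dtype=np.int64)
    for ac, an in pairs:
        totals += _sample_hypergeom(rng, ac, an, draws, iterations)
    counts = np.bincount(totals)
    return BurdenDistribution(
        unit_id=unit.unit_id,
        ancestry=ancestry,
        iterations=iterations,
        counts=counts,
        seed=seed,
        draws=totals if keep_draws else None,
    )


def exact_burden_distribution(
    db: Mapping[VariantKey, PopulationVariantStats],
    unit: AggregationUnit,
    ancestry: AncestryLabel,
    n_pop: int,
    max_variants: int = 20,
    max_support: int = 100_000,
    allele_draws: int | None = None,
) -> np.ndarray:
    """Exact probability vector of the simulated burden (test oracle).

    Convolution of per-variant hypergeometric PMFs under the engine's
    independence assumption; guarded to oracle scale.
    """
    pairs = _unit_variant_stats(db, unit.member_keys, ancestry)
    if len(pairs) > max_variants:
        raise ValueError(
            f"{len(pairs)} variants exceeds the exact-oracle guard of "
            f"{max_variants}; use the Monte-Carlo engine"
        )
    draws = 2 * n_pop if allele_draws is None else allele_draws
    pmf = np.array([1.0])
    for ac, an in pairs:
        if an < draws:
            raise ValueError(f"AN={an} smaller than {draws} allele draws")
        support = min(ac, draws)
        k = np.arange(support + 1)
        pmf_v = stats.hypergeom.pmf(k, an, ac, draws)
        pmf = np.convolve(pmf, pmf_v)
        if len(pmf) > max_support:
            raise ValueError("support exceeds the exact-oracle scale guard")
    return pmf / pmf.sum()


def empirical_pvalue(
    dist: BurdenDistribution,
    b: int,
    randomize: bool = False,
    rng: np.random.Generator | None = None,
) -> float:
    """Add-one empirical tail probability Pr(X >= b).

    With ``randomize=True`` the p-value is drawn uniformly over the interval
    spanned by the discrete mass at b, which makes null p-values exactly
    uniform (used for calibration diagnostics, never for reporting).
    """
    n = dist.iterations
    tail = dist.tail_count(b)
    if not randomize:
        return (tail + 1) / (n + 1)
    gt = dist.tail_count(b + 1)
    eq = tail - gt
    u = (rng or np.random.default_rng()).random()
    return (gt + u * (eq + 1)) / (n + 1)


def format_pvalue(p: float, iterations: int) -> str:
    """Human-readable p; saturated results display as '< 1/iterations'."""
    if p <= 1.0 / (iterations + 1):
        return f"< {1.0 / iterations:.0e}"
    return f"{p:.3g}"


def combine_ancestries(
    dists: Mapping[AncestryLabel, BurdenDistribution],
    b_pop: Mapping[AncestryLabel, int],
) -> tuple[float, BurdenDistribution]:
    """Combined p from the joint per-iteration burden across ancestries."""
    if not dists:
        raise ValueError("no ancestry distributions to combine")
    its = {d.iterations for d in dists.values()}
    if len(its) != 1:
        raise ValueError(f"mismatched iteration counts: {sorted(its)}")
    iterations = its.pop()
    totals = np.zeros(iterations, dtype=np.int64)
    unit_ids = set()
    for pop, d in dists.items():
        if d.draws is None:
            raise ValueError("combining requires per-iteration draws (keep_draws=True)")
        totals += d.draws
        unit_ids.add(d.unit_id)
    b_total = sum(b_pop.get(pop, 0) for pop in dists)
    joint = BurdenDistribution(
        unit_id=unit_ids.pop() if len(unit_ids) == 1 else "+".join(sorted(unit_ids)),
        ancestry=AncestryLabel.UNKNOWN,
        iterations=iterations,
        counts=np.bincount(totals),
        draws=totals,
    )
    return empirical_pvalue(joint, b_total), joint


def observed_burden(
    cohort: CohortGenotypeMatrix,
    qualifying: set[VariantKey],
    unit: AggregationUnit,
    ancestry: AncestryLabel,
    scale: str = "alleles",
) -> int:
    """Aggregate observed burden of the unit in one ancestry group.

    ``alleles`` sums alternate-allele dosage (hom = 2); ``carriers`` counts
    individuals with any qualifying allele.  Missing genotypes contribute 0.
    """
    if not unit.member_keys:
        raise ValueError(f"unit {unit.unit_id} has no member variants")
    cols = cohort.sample_indices(ancestry)
    if cols.size == 0:
        return 0
    rows = [
        cohort.variant_index(k)
        for k in unit.member_keys
        if k in qualifying and k in cohort._index
    ]
    if not rows:
        return 0
    d = cohort.dosage[np.ix_(rows, cols)].astype(np.int64)
    d = np.where(d == MISSING, 0, d)
    if scale == "carriers":
        return int((d.sum(axis=0) > 0).sum())
    return int(d.sum())


def _expected_mean(
    db: Mapping[VariantKey, PopulationVariantStats],
    members: Iterable[VariantKey],
    ancestry: AncestryLabel,
    n_pop: int,
) -> float:
    """Closed-form mean simulated burden: sum of AC * 2N / AN."""
    return sum(ac * (2 * n_pop) / an for ac, an in _unit_variant_stats(db, members, ancestry))


def _tested_groups(
    cohort: CohortGenotypeMatrix, min_group_size: int
) -> dict[AncestryLabel, int]:
    sizes = cohort.ancestry_sizes()
    return {
        pop: n
        for pop, n in sizes.items()
        if pop in CONTINENTAL_ANCESTRIES and n >= min_group_size
    }


def _result_flags(
    cohort: CohortGenotypeMatrix,
    db: Mapping[VariantKey, PopulationVariantStats],
    members: Sequence[VariantKey],
    tested: Mapping[AncestryLabel, int],
    config: BurdenConfig,
) -> tuple[set[str], int]:
    """var1 / af5 annotations plus the observed-variant count."""
    flags: set[str] = set()
    tested_cols = np.concatenate(
        [cohort.sample_indices(pop) for pop in tested]
    ) if tested else np.array([], dtype=int)
    n_observed = 0
    af5 = False
    for key in members:
        if key not in cohort._index:
            continue
        row = cohort.dosage[cohort.variant_index(key)][tested_cols]
        called = row != MISSING
        alt = np.where(called, row, 0).sum()
        if alt > 0:
            n_observed += 1
            cohort_af = alt / (2 * max(int(called.sum()), 1))
            rec = db.get(key)
            db_af_max = max((rec.af(p) for p in tested), default=0.0) if rec else 0.0
            if cohort_af > config.af5_cohort_af and db_af_max < config.af5_db_af:
                af5 = True
    if n_observed == 1:
        flags.add("var1")
    if af5:
        flags.add("af5")
    return flags, n_observed


def _run_units(
    units: Sequence[AggregationUnit],
    cohort: CohortGenotypeMatrix,
    db: Mapping[VariantKey, PopulationVariantStats],
    qualifying: set[VariantKey],
    soft_notes: Mapping[VariantKey, set[str]],
    config: BurdenConfig,
) -> list[BurdenResult]:
    tested = _tested_groups(cohort, config.min_group_size)
    if not tested:
        raise ValueError("no ancestry group meets the minimum size for testing")
    results = []
    seed_seq = np.random.SeedSequence(config.seed)
    for unit, child in zip(units, seed_seq.spawn(len(units))):
        members = sorted(unit.member_keys & qualifying, key=lambda k: k.packed)
        if not members:
            results.append(
                BurdenResult(
                    unit_id=unit.unit_id, b_pop={}, p_pop={}, combined_p=None,
                    display_p="NA",
                )
            )
            continue
        subunit = AggregationUnit(unit.unit_id, unit.level, frozenset(members))
        rng = np.random.default_rng(child)
        b_pop: dict[AncestryLabel, int] = {}
        p_pop: dict[AncestryLabel, float] = {}
        dists: dict[AncestryLabel, BurdenDistribution] = {}
        expected = 0.0
        for pop in sorted(tested, key=lambda a: a.value):
            n_pop = tested[pop]
            if not _unit_variant_stats(db, members, pop):
                continue
            b = observed_burden(cohort, qualifying, subunit, pop, config.burden_scale)
            dist = simulate_burden_distribution(
                db, subunit, pop, n_pop,
                iterations=config.iterations, rng=rng, keep_draws=True,
            )
            b_pop[pop] = b
            p_pop[pop] = empirical_pvalue(dist, b)
            dists[pop] = dist
            expected += _expected_mean(db, members, pop, n_pop)
        if not dists:
            results.append(
                BurdenResult(
                    unit_id=unit.unit_id, b_pop={}, p_pop={}, combined_p=None,
                    display_p="NA",
                )
            )
            continue
        combined_p, joint = combine_ancestries(dists, b_pop)
        combined_p_rand = None
        if config.randomized_p:
            combined_p_rand = empirical_pvalue(
                joint, sum(b_pop.values()), randomize=True, rng=rng
            )
        flags, n_obs = _result_flags(cohort, db, members, tested, config)
        notes = {
            str(k): soft_notes[k] for k in members if k in soft_notes
        }
        results.append(
            BurdenResult(
                unit_id=unit.unit_id,
                b_pop=b_pop,
                p_pop=p_pop,
                combined_p=combined_p,
                combined_p_randomized=combined_p_rand,
                flags=flags,
                soft_filter_notes=notes,
                n_variants_observed=n_obs,
                n_variants_expected_mean=expected,
                b_total=sum(b_pop.values()),
                display_p=format_pvalue(combined_p, config.iterations),
                exome_wide_significant=combined_p < config.exome_wide_alpha,
            )
        )
    return results


def _prepare(
    cohort: CohortGenotypeMatrix,
    db: Mapping[VariantKey, PopulationVariantStats],
    annotations: Mapping[VariantKey, VariantAnnotation],
    config: BurdenConfig,
    lcr=None,
    calling_regions: IntervalIndex | None = None,
    cadd_min: float | None = None,
) -> tuple[set[VariantKey], dict[VariantKey, set[str]]]:
    """Filters -> harmonization -> qualifying selection -> cohort LD prune."""
    db_flags = _filters.apply_population_filters(db, calling_regions)
    cohort_flags = _filters.site_quality_filters(cohort).merged_with(
        _filters.ac0_flag(cohort)
    )
    all_variants = set(cohort.variants) | set(db)
    excluded, soft_notes = _filters.reciprocal_harmonize(
        cohort_flags, db_flags, lcr, all_variants
    )
    tested = _tested_groups(cohort, config.min_group_size)
    qualifying = _filters.select_qualifying_variants(
        annotations, db,
        af_max=config.af_max,
        cadd_min=config.cadd_min if cadd_min is None else cadd_min,
        consequence_set=config.consequence_set,
        tested_ancestries=tested or CONTINENTAL_ANCESTRIES,
    )
    qualifying -= excluded
    pruned = _ld.prune_cohort_ld(
        cohort, qualifying, window=config.ld_window, r2_min=config.cohort_r2_min
    )
    if pruned:
        logger.info("cohort LD pruning removed %d variants", len(pruned))
    return qualifying - pruned, soft_notes


def run_gene_burden(
    cohort: CohortGenotypeMatrix,
    db: Mapping[VariantKey, PopulationVariantStats],
    annotations: Mapping[VariantKey, VariantAnnotation],
    config: BurdenConfig | None = None,
    lcr=None,
    calling_regions: IntervalIndex | None = None,
    genes: Iterable[str] | None = None,
) -> list[BurdenResult]:
    """Gene-level burden testing across all tested ancestries, combined."""
    config = config or BurdenConfig()
    qualifying, soft_notes = _prepare(cohort, db, annotations, config, lcr, calling_regions)
    by_gene: dict[str, set[VariantKey]] = {}
    for key in qualifying:
        ann = annotations.get(key)
        if ann is None:
            continue
        by_gene.setdefault(ann.gene_id, set()).add(key)
    gene_list = sorted(by_gene) if genes is None else [g for g in genes if g in by_gene]
    units = [
        AggregationUnit(g, "gene", frozenset(by_gene[g])) for g in gene_list
    ]
    return _run_units(units, cohort, db, qualifying, soft_notes, config)


def run_domain_burden(
    cohort: CohortGenotypeMatrix,
    db: Mapping[VariantKey, PopulationVariantStats],
    annotations: Mapping[VariantKey, VariantAnnotation],
    domains: Mapping[str, tuple[str, Sequence[GenomicInterval]]],
    gene_shortlist: Iterable[str],
    config: BurdenConfig | None = None,
    lcr=None,
    calling_regions: IntervalIndex | None = None,
) -> list[BurdenResult]:
    """Domain-level burden testing with no CADD filter (cadd_min = 0).

    ``domains`` maps domain id -> (gene id, genomic intervals).  Domains of
    genes outside the shortlist are skipped; domains with no mappable
    qualifying variants yield an NA result rather than being dropped.
    """
    config = config or BurdenConfig()
    shortlist = set(gene_shortlist)
    qualifying, soft_notes = _prepare(
        cohort, db, annotations, config, lcr, calling_regions, cadd_min=0.0
    )
    units = []
    for domain_id, (gene_id, intervals) in sorted(domains.items()):
        if gene_id not in shortlist:
            continue
        index = IntervalIndex(intervals)
        members = {
            key for key in qualifying
            if annotations.get(key) is not None
            and annotations[key].gene_id == gene_id
            and index.overlaps(key.chrom, key.pos - 1, key.pos - 1 + len(key.ref))
        }
        units.append(AggregationUnit(domain_id, "domain", frozenset(members)))
    return _run_units(units, cohort, db, qualifying, soft_notes, config)
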
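import numpy as np
import pytest
from scipy import stats

from burdensim.engine import (
    BurdenConfig,
    BurdenDistribution,
    combine_ancestries,
    empirical_pvalue,
    exact_burden_distribution,
    format_pvalue,
    observed_burden,
    run_domain_burden,
    run_gene_burden,
    simulate_burden_distribution,
)
from burdensim.intervals import GenomicInterval
from burdensim.keys import VariantKey
from burdensim.types import AncestryLabel, AggregationUnit, MISSING

from conftest import make_annotation, make_cohort, make_db

EUR, AFR = AncestryLabel.EUR, AncestryLabel.AFR


def _single_variant_db(ac, an, pop=EUR, pos=1000):
    key = VariantKey("1", pos, "A", "T")
    return key, make_db({key: {pop: (ac, an)}})


def _unit(*keys):
    return AggregationUnit("u", "gene", frozenset(keys))


class TestObservedBurden:
    def test_hand_count(self):
        # 12 het carriers, one carrying 3 distinct variants -> 14 alleles
        n_samples = 20
        dosage = np.zeros((3, n_samples), dtype=np.int8)
        dosage[0, 0:10] = 1  # 10 carriers of v0
        dosage[1, 10] = 1
        dosage[2, 11] = 1
        dosage[1, 0] = 1  # sample 0 carries v0, v1, v2
        dosage[2, 0] = 1
        cohort = make_cohort(dosage)
        unit = _unit(*cohort.variants)
        b = observed_burden(cohort, set(cohort.variants), unit, EUR)
        assert b == 14
        carriers = observed_burden(cohort, set(cohort.variants), unit, EUR, scale="carriers")
        assert carriers == 12

    def test_no_carriers(self):
        cohort = make_cohort(np.zeros((2, 5), dtype=np.int8))
        assert observed_burden(cohort, set(cohort.variants), _unit(*cohort.variants), EUR) == 0

    def test_homozygote_counts_two(self):
        dosage = np.zeros((1, 5), dtype=np.int8)
        dosage[0, 0] = 2
        cohort = make_cohort(dosage)
        assert observed_burden(cohort, set(cohort.variants), _unit(*cohort.variants), EUR) == 2

    def test_empty_unit_errors(self):
        cohort = make_cohort(np.zeros((1, 5), dtype=np.int8))
        with pytest.raises(ValueError, match="no member"):
            observed_burden(cohort, set(), AggregationUnit("e", "gene", frozenset()), EUR)

    def test_missing_counts_zero(self):
        dosage = np.array([[MISSING, 1, 2]], dtype=np.int8)
        cohort = make_cohort(dosage)
        assert observed_burden(cohort, set(cohort.variants), _unit(*cohort.variants), EUR) == 3


class TestExactDistribution:
    def test_single_variant_tail(self):
        key, db = _single_variant_db(2, 10)
        pmf = exact_burden_distribution(db, _unit(key), EUR, 0, allele_draws=5)
        assert 1 - pmf[0] == pytest.approx(7 / 9)
        assert pmf.sum() == pytest.approx(1.0)

    def test_two_iid_variants_self_convolution(self):
        k1 = VariantKey("1", 1000, "A", "T")
        k2 = VariantKey("1", 2000, "A", "T")
        db = make_db({k1: {EUR: (3, 40)}, k2: {EUR: (3, 40)}})
        single = exact_burden_distribution(db, _unit(k1), EUR, 4)
        double = exact_burden_distribution(db, _unit(k1, k2), EUR, 4)
        np.testing.assert_allclose(double, np.convolve(single, single), atol=1e-12)

    def test_scale_guard(self):
        keys = [VariantKey("1", 1000 + i, "A", "T") for i in range(25)]
        db = make_db({k: {EUR: (1, 100)} for k in keys})
        with pytest.raises(ValueError, match="oracle"):
            exact_burden_distribution(db, AggregationUnit("u", "gene", frozenset(keys)), EUR, 5)


class TestSimulation:
    def test_point_mass_at_zero_when_ac_zero(self):
        key, db = _single_variant_db(0, 1000)
        dist = simulate_burden_distribution(db, _unit(key), EUR, 10, iterations=5000, seed=0)
        assert dist.counts.tolist() == [5000]

    def test_mean_matches_closed_form(self):
        k1 = VariantKey("1", 1000, "A", "T")
        k2 = VariantKey("1", 2000, "A", "T")
        db = make_db({k1: {EUR: (40, 10_000)}, k2: {EUR: (15, 8_000)}})
        n_pop = 50
        dist = simulate_burden_distribution(
            db, _unit(k1, k2), EUR, n_pop, iterations=100_000, seed=3, keep_draws=True
        )
        analytic = 40 * 100 / 10_000 + 15 * 100 / 8_000
        assert dist.draws.mean() == pytest.approx(analytic, rel=0.01)

    def test_population_smaller_than_cohort_errors(self):
        key, db = _single_variant_db(2, 10)
        with pytest.raises(ValueError, match="smaller"):
            simulate_burden_distribution(db, _unit(key), EUR, 6, iterations=10)

    def test_deterministic_under_seed(self):
        key, db = _single_variant_db(5, 500)
        d1 = simulate_burden_distribution(db, _unit(key), EUR, 20, iterations=20_000, seed=9)
        d2 = simulate_burden_distribution(db, _unit(key), EUR, 20, iterations=20_000, seed=9)
        assert d1.counts.tolist() == d2.counts.tolist()

    def test_histogram_mass_equals_iterations(self):
        key, db = _single_variant_db(5, 500)
        dist = simulate_burden_distribution(db, _unit(key), EUR, 20, iterations=12_345, seed=1)
        assert dist.counts.sum() == 12_345

    @pytest.mark.parametrize("ac,an,n_pop", [(2, 40, 5), (10, 100, 10), (20, 200, 20)])
    def test_tv_distance_vs_oracle(self, ac, an, n_pop):
        key, db = _single_variant_db(ac, an)
        dist = simulate_burden_distribution(db, _unit(key), EUR, n_pop, iterations=100_000, seed=4)
        pmf = exact_burden_distribution(db, _unit(key), EUR, n_pop)
        emp = dist.counts / dist.iterations
        width = max(len(emp), len(pmf))
        emp = np.pad(emp, (0, width - len(emp)))
        pmf = np.pad(pmf, (0, width - len(pmf)))
        assert 0.5 * np.abs(emp - pmf).sum() < 0.01


class TestEmpiricalPvalue:
    def _dist(self, counts, iterations=None):
        counts = np.asarray(counts)
        return BurdenDistribution(
            "u", EUR, int(counts.sum()) if iterations is None else iterations, counts
        )

    def test_b_zero_gives_one(self):
        dist = self._dist([70, 20, 10])
        assert empirical_pvalue(dist, 0) == 1.0

    def test_add_one_floor(self):
        dist = self._dist([1000])  # point mass at 0
        assert empirical_pvalue(dist, 1) == pytest.approx(1 / 1001)

    def test_saturated_display(self):
        p = 1 / (10**6 + 1)
        assert format_pvalue(p, 10**6) == "< 1e-06"
        assert format_pvalue(0.123, 10**6) == "0.123"

    def test_non_increasing_in_b(self):
        dist = self._dist([50, 30, 15, 5])
        ps = [empirical_pvalue(dist, b) for b in range(6)]
        assert ps == sorted(ps, reverse=True)
        assert ps[0] == 1.0

    def test_randomized_p_uniform_under_null(self, rng):
        # PIT property: X drawn from the same distribution as the histogram
        pmf = np.array([0.5, 0.3, 0.2])
        counts = (pmf * 10_000).astype(int)
        dist = self._dist(counts)
        bs = rng.choice(3, p=pmf, size=4000)
        ps = np.array([empirical_pvalue(dist, int(b), randomize=True, rng=rng) for b in bs])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestCombine:
    def test_single_ancestry_identity(self):
        key, db = _single_variant_db(5, 1000)
        dist = simulate_burden_distribution(db, _unit(key), EUR, 20, iterations=30_000,
                                            seed=2, keep_draws=True)
        combined, _ = combine_ancestries({EUR: dist}, {EUR: 3})
        assert combined == empirical_pvalue(dist, 3)

    def test_point_mass_combination(self):
        z = np.zeros(1000, dtype=np.int64)
        d1 = BurdenDistribution("u", EUR, 1000, np.bincount(z), draws=z)
        d2 = BurdenDistribution("u", AFR, 1000, np.bincount(z), draws=z)
        combined, _ = combine_ancestries({EUR: d1, AFR: d2}, {EUR: 2, AFR: 1})
        assert combined == pytest.approx(1 / 1001)

    def test_mismatched_iterations_error(self):
        z1, z2 = np.zeros(100, dtype=np.int64), np.zeros(200, dtype=np.int64)
        d1 = BurdenDistribution("u", EUR, 100, np.bincount(z1), draws=z1)
        d2 = BurdenDistribution("u", AFR, 200, np.bincount(z2), draws=z2)
        with pytest.raises(ValueError, match="mismatched"):
            combine_ancestries({EUR: d1, AFR: d2}, {})

    def test_two_ancestry_joint_vs_convolution_oracle(self):
        k1 = VariantKey("1", 1000, "A", "T")
        k2 = VariantKey("1", 50_000, "A", "T")
        db = make_db({k1: {EUR: (4, 200), AFR: (6, 300)},
                      k2: {EUR: (2, 200), AFR: (1, 300)}})
        unit = _unit(k1, k2)
        rng_seed = 11
        dists = {
            pop: simulate_burden_distribution(
                db, unit, pop, 15, iterations=100_000, seed=rng_seed + i, keep_draws=True
            )
            for i, pop in enumerate((EUR, AFR))
        }
        _, joint = combine_ancestries(dists, {EUR: 0, AFR: 0})
        oracle = np.convolve(
            exact_burden_distribution(db, unit, EUR, 15),
            exact_burden_distribution(db, unit, AFR, 15),
        )
        emp = joint.counts / joint.iterations
        width = max(len(emp), len(oracle))
        emp = np.pad(emp, (0, width - len(emp)))
        oracle = np.pad(oracle, (0, width - len(oracle)))
        assert 0.5 * np.abs(emp - oracle).sum() < 0.01


def _pipeline_fixture(n_eur=15, n_afr=15):
    """Two genes x two variants, clean quality fields."""
    keys = {
        "g1v1": VariantKey("1", 10_000, "A", "T"),
        "g1v2": VariantKey("1", 40_000, "A", "T"),
        "g2v1": VariantKey("2", 10_000, "A", "T"),
        "g2v2": VariantKey("2", 40_000, "A", "T"),
    }
    db = make_db({
        keys["g1v1"]: {EUR: (10, 10_000), AFR: (10, 10_000)},
        keys["g1v2"]: {EUR: (5, 10_000), AFR: (5, 10_000)},
        keys["g2v1"]: {EUR: (10, 10_000), AFR: (10, 10_000)},
        keys["g2v2"]: {EUR: (5, 10_000), AFR: (5, 10_000)},
    })
    ann = {
        k: make_annotation(
            k,
            gene="G1" if name.startswith("g1") else "G2",
            af={EUR: db[k].af(EUR), AFR: db[k].af(AFR)},
        )
        for name, k in keys.items()
    }
    n = n_eur + n_afr
    dosage = np.zeros((4, n), dtype=np.int8)
    cohort = make_cohort(
        dosage,
        ancestry_labels=[EUR] * n_eur + [AFR] * n_afr,
        variants=list(keys.values()),
    )
    return keys, db, ann, cohort


class TestRunGeneBurden:
    def test_var1_flag(self):
        keys, db, ann, cohort = _pipeline_fixture()
        row = cohort.variant_index(keys["g1v1"])
        cohort.dosage[row, 0:4] = 1
        config = BurdenConfig(iterations=5_000, seed=1)
        results = {r.unit_id: r for r in run_gene_burden(cohort, db, ann, config)}
        assert "var1" in results["G1"].flags
        assert results["G1"].n_variants_observed == 1
        assert results["G1"].b_total == 4

    def test_af5_flag(self):
        keys, db, ann, cohort = _pipeline_fixture()
        row = cohort.variant_index(keys["g1v1"])
        cohort.dosage[row, 0:6] = 1  # cohort AF = 6/60 = 10% vs db 0.1%
        config = BurdenConfig(iterations=5_000, seed=1)
        results = {r.unit_id: r for r in run_gene_burden(cohort, db, ann, config)}
        assert "af5" in results["G1"].flags

    def test_expected_mean_closed_form(self):
        keys, db, ann, cohort = _pipeline_fixture()
        config = BurdenConfig(iterations=2_000, seed=1)
        results = {r.unit_id: r for r in run_gene_burden(cohort, db, ann, config)}
        want = sum(
            db[k].ac[pop] * 30 / db[k].an[pop]
            for k in (keys["g1v1"], keys["g1v2"])
            for pop in (EUR, AFR)
        )
        assert results["G1"].n_variants_expected_mean == pytest.approx(want, abs=1e-9)

    def test_zero_tested_ancestries_errors(self):
        keys, db, ann, cohort = _pipeline_fixture(n_eur=5, n_afr=5)
        with pytest.raises(ValueError, match="minimum size"):
            run_gene_burden(cohort, db, ann, BurdenConfig(iterations=100))

    def test_determinism(self):
        keys, db, ann, cohort = _pipeline_fixture()
        cohort.dosage[0, 0:3] = 1
        config = BurdenConfig(iterations=10_000, seed=42)
        r1 = run_gene_burden(cohort, db, ann, config)
        r2 = run_gene_burden(cohort, db, ann, config)
        assert [(r.unit_id, r.combined_p, tuple(sorted(r.p_pop.values()))) for r in r1] == [
            (r.unit_id, r.combined_p, tuple(sorted(r.p_pop.values()))) for r in r2
        ]


class TestRunDomainBurden:
    def test_domain_equals_gene_when_covering(self):
        keys, db, ann, cohort = _pipeline_fixture()
        cohort.dosage[cohort.variant_index(keys["g1v1"]), 0:3] = 1
        config = BurdenConfig(iterations=20_000, seed=5, cadd_min=0.0)
        gene = {r.unit_id: r for r in run_gene_burden(cohort, db, ann, config)}
        domains = {"D_all": ("G1", [GenomicInterval("1", 0, 100_000)])}
        dom = run_domain_burden(cohort, db, ann, domains, ["G1"], config)[0]
        assert dom.b_total == gene["G1"].b_total
        assert dom.combined_p == pytest.approx(gene["G1"].combined_p)

    def test_empty_domain_reports_na(self):
        keys, db, ann, cohort = _pipeline_fixture()
        domains = {"D_empty": ("G1", [GenomicInterval("1", 90_000, 95_000)])}
        config = BurdenConfig(iterations=1_000, seed=5)
        out = run_domain_burden(cohort, db, ann, domains, ["G1"], config)
        assert len(out) == 1
        assert out[0].combined_p is None and out[0].display_p == "NA"

    def test_concentrated_domain_beats_gene(self):
        # all the observed burden lives in a sub-domain with fewer members:
        # same observed count against a smaller simulated background
        keys, db, ann, cohort = _pipeline_fixture()
        cohort.dosage[cohort.variant_index(keys["g1v1"]), 0:5] = 1
        config = BurdenConfig(iterations=50_000, seed=6, cadd_min=0.0)
        gene = {r.unit_id: r for r in run_gene_burden(cohort, db, ann, config)}
        domains = {"D_v1": ("G1", [GenomicInterval("1", 9_000, 11_000)])}
        dom = run_domain_burden(cohort, db, ann, domains, ["G1"], config)[0]
        assert dom.combined_p <= gene["G1"].combined_p
        # exact-oracle cross-check on both unit definitions
        unit_dom = _unit(keys["g1v1"])
        unit_gene = _unit(keys["g1v1"], keys["g1v2"])
        for pop, n in ((EUR, 15), (AFR, 15)):
            p_dom = exact_burden_distribution(db, unit_dom, pop, n)
            p_gene = exact_burden_distribution(db, unit_gene, pop, n)
            b = 5 if pop == EUR else 0
            tail = lambda pmf, b: pmf[min(b, len(pmf) - 1):].sum() if b < len(pmf) else 0.0
            assert tail(p_dom, b) <= tail(p_gene, b) + 1e-12
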
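import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from burdensim.filters import (
    FilterFlagSet,
    HARD_FLAGS,
    SOFT_FLAGS,
    ac0_flag,
    apply_population_filters,
    excess_het_phred,
    hwe_exact_p,
    reciprocal_harmonize,
    select_qualifying_variants,
    site_quality_filters,
)
from burdensim.intervals import GenomicInterval, IntervalIndex
from burdensim.keys import VariantKey
from burdensim.mask import MaskTrack
from burdensim.types import MISSING, AncestryLabel

from conftest import make_annotation, make_cohort, make_db

EUR = AncestryLabel.EUR
AFR = AncestryLabel.AFR


def hwe_enumeration_oracle(hom_ref, het, hom_alt):
    """Exact-rational enumeration of the conditional het distribution."""
    n = hom_ref + het + hom_alt
    n_alt = 2 * hom_alt + het
    if n_alt == 0 or n_alt == 2 * n:
        return Fraction(1)
    weights = {}
    for h in range(n_alt % 2, min(n_alt, 2 * n - n_alt) + 1, 2):
        aa = (n_alt - h) // 2
        rr = n - aa - h
        weights[h] = Fraction(
            math.factorial(n) * 2**h,
            math.factorial(rr) * math.factorial(h) * math.factorial(aa),
        )
    total = sum(weights.values())
    p_obs = weights[het]
    return sum(w for w in weights.values() if w <= p_obs) / total


def test_hwe_two_individuals():
    # (1,0,1): P(het=0)=1/3, P(het=2)=2/3 -> p = 1/3
    assert hwe_exact_p(1, 0, 1) == pytest.approx(1 / 3)


def test_hwe_monomorphic():
    assert hwe_exact_p(10, 0, 0) == 1.0


def test_hwe_all_het_tail():
    assert hwe_exact_p(0, 50, 0) == pytest.approx(
        float(hwe_enumeration_oracle(0, 50, 0)), rel=1e-9
    )


def test_hwe_exact_proportions_not_flagged():
    assert hwe_exact_p(25, 50, 25) > 0.001


def test_hwe_exhaustive_small_n():
    # every genotype configuration with n <= 20 against the rational oracle
    for n in range(1, 21):
        for het in range(n + 1):
            for ha in range(n - het + 1):
                hr = n - het - ha
                got = hwe_exact_p(hr, het, ha)
                want = float(hwe_enumeration_oracle(hr, het, ha))
                assert got == pytest.approx(want, rel=1e-9, abs=1e-12), (hr, het, ha)


@given(
    st.integers(min_value=0, max_value=40),
    st.integers(min_value=0, max_value=40),
    st.integers(min_value=0, max_value=40),
)
def test_hwe_is_probability(hr, het, ha):
    if hr + het + ha == 0:
        return
    p = hwe_exact_p(hr, het, ha)
    assert 0.0 < p <= 1.0


def test_excess_het_phred_direction():
    # an all-het site is extreme heterozygote excess
    assert excess_het_phred(0, 40, 0) > 100
    assert excess_het_phred(30, 8, 1) < 20


def test_population_filters():
    k_ok = VariantKey("1", 100, "A", "T")
    k_low = VariantKey("1", 200, "A", "T")
    k_fail = VariantKey("1", 300, "A", "T")
    db = make_db({k_ok: {EUR: (5, 10_000)}}, n_called=100_000)
    db.update(make_db({k_low: {EUR: (5, 10_000)}}, n_called=4_999))
    db.update(make_db({k_fail: {EUR: (5, 10_000)}}, qc_pass=False))
    flags = apply_population_filters(db)
    assert k_low in flags.variants_with("ns5000")
    assert k_fail in flags.variants_with("db_qc_fail")
    assert not any(k_ok in ks for ks in flags.flags.values())


def test_population_filter_calling_regions():
    k_in = VariantKey("1", 150, "A", "T")  # 0-based 149 inside [100, 200)
    k_out = VariantKey("1", 500, "A", "T")
    db = make_db({k_in: {EUR: (1, 10_000)}, k_out: {EUR: (1, 10_000)}})
    regions = IntervalIndex([GenomicInterval("1", 100, 200)])
    flags = apply_population_filters(db, regions)
    assert k_out in flags.variants_with("gnomadDP0")
    assert k_in not in flags.variants_with("gnomadDP0")
    # interval-membership oracle over all positions
    for pos in range(90, 210):
        key = VariantKey("1", pos, "A", "T")
        sub = apply_population_filters(make_db({key: {EUR: (1, 10_000)}}), regions)
        assert (key in sub.variants_with("gnomadDP0")) == (not 100 <= pos - 1 < 200)


def test_sor_flag():
    cohort = make_cohort([[1, 0], [1, 0]], sor=[3.5, 2.0])
    flags = site_quality_filters(cohort)
    assert cohort.variants[0] in flags.variants_with("sor")
    assert cohort.variants[1] not in flags.variants_with("sor")


def test_sor_absent_skipped(caplog):
    cohort = make_cohort([[1, 0]], sor=[np.nan])
    flags = site_quality_filters(cohort)
    assert flags.variants_with("sor") == set()
    assert "skipped" in caplog.text


def test_missing_fraction_flag():
    dosage = np.zeros((1, 150), dtype=np.int8)
    dosage[0, :2] = MISSING  # 2/150 = 1.33% > 1%
    cohort = make_cohort(dosage)
    flags = site_quality_filters(cohort)
    assert cohort.variants[0] in flags.variants_with("missing")


def test_hwe_proportions_no_flag():
    dosage = np.array([[0] * 25 + [1] * 50 + [2] * 25], dtype=np.int8)
    cohort = make_cohort(dosage)
    flags = site_quality_filters(cohort)
    assert cohort.variants[0] not in flags.variants_with("hwe")


def test_excesshet_soft_flag_all_het():
    dosage = np.ones((1, 200), dtype=np.int8)
    cohort = make_cohort(dosage)
    flags = site_quality_filters(cohort)
    assert cohort.variants[0] in flags.variants_with("excesshet")
    assert cohort.variants[0] in flags.variants_with("hwe")


def _carrier_cohort(carriers):
    """carriers: list of (ab, dp, gq) heterozygous carriers plus 5 hom-refs."""
    n = len(carriers) + 5
    dosage = np.array([[1] * len(carriers) + [0] * 5], dtype=np.int8)
    dp = np.full((1, n), 50, dtype=np.int32)
    gq = np.full((1, n), 99, dtype=np.int32)
    ab = np.full((1, n), np.nan)
    for j, (a, d, g) in enumerate(carriers):
        ab[0, j] = a
        dp[0, j] = d
        gq[0, j] = g
    return make_cohort(dosage, dp=dp, gq=gq, ab=ab)


def test_ac0_single_skewed_carrier():
    cohort = _carrier_cohort([(0.10, 50, 99)])
    assert cohort.variants[0] in ac0_flag(cohort).variants_with("AC0")


def test_ac0_skewed_plus_low_quality():
    cohort = _carrier_cohort([(0.15, 40, 99), (0.5, 8, 15)])
    assert cohort.variants[0] in ac0_flag(cohort).variants_with("AC0")


def test_ac0_passing_carrier():
    cohort = _carrier_cohort([(0.5, 30, 60)])
    assert ac0_flag(cohort).variants_with("AC0") == set()


def test_ac0_no_carriers_not_flagged():
    cohort = make_cohort(np.zeros((1, 10), dtype=np.int8))
    assert ac0_flag(cohort).variants_with("AC0") == set()


def test_ac0_low_depth_but_good_gq_passes():
    # the low-quality clause needs BOTH DP<10 AND GQ<20
    cohort = _carrier_cohort([(0.5, 8, 60)])
    assert ac0_flag(cohort).variants_with("AC0") == set()


def _annotations():
    k1 = VariantKey("1", 100, "A", "T")
    k2 = VariantKey("1", 200, "A", "T")
    k3 = VariantKey("1", 300, "A", "T")
    k4 = VariantKey("1", 400, "A", "T")
    return {
        k1: make_annotation(k1, cadd=25.0, af={EUR: 0.005, AFR: 0.02}),
        k2: make_annotation(k2, cadd=19.9, af={EUR: 0.001, AFR: 0.001}),
        k3: make_annotation(k3, consequence="synonymous", cadd=25.0, af={EUR: 0.001}),
        k4: make_annotation(k4, cadd=None, af={EUR: 0.0001}),
    }


def test_qualifying_per_population_af_rule():
    ann = _annotations()
    out = select_qualifying_variants(ann, tested_ancestries=[EUR, AFR])
    assert VariantKey("1", 100, "A", "T") not in out  # AFR AF 2% fails


def test_qualifying_cadd_threshold():
    ann = _annotations()
    k2 = VariantKey("1", 200, "A", "T")
    assert k2 not in select_qualifying_variants(ann, cadd_min=20.0)
    assert k2 in select_qualifying_variants(ann, cadd_min=0.0)


def test_qualifying_consequence_rule():
    ann = _annotations()
    assert VariantKey("1", 300, "A", "T") not in select_qualifying_variants(ann, cadd_min=0.0)


def test_qualifying_absent_cadd():
    ann = _annotations()
    k4 = VariantKey("1", 400, "A", "T")
    assert k4 not in select_qualifying_variants(ann, cadd_min=20.0)
    assert k4 in select_qualifying_variants(ann, cadd_min=0.0)


def test_qualifying_monotone_in_thresholds():
    ann = _annotations()
    sizes_cadd = [
        len(select_qualifying_variants(ann, cadd_min=c)) for c in (0.0, 10.0, 20.0, 30.0)
    ]
    assert sizes_cadd == sorted(sizes_cadd, reverse=True)
    sizes_af = [
        len(select_qualifying_variants(ann, af_max=a, cadd_min=0.0))
        for a in (1e-4, 1e-3, 1e-2, 1e-1)
    ]
    assert sizes_af == sorted(sizes_af)


def test_reciprocity_db_failure_excludes_cohort_variant():
    key = VariantKey("1", 100, "A", "T")
    db_flags = FilterFlagSet()
    db_flags.add("db_qc_fail", key)
    excluded, soft = reciprocal_harmonize(FilterFlagSet(), db_flags, None, [key])
    assert key in excluded and soft == {}


def test_soft_flag_retained_as_annotation():
    key = VariantKey("1", 100, "A", "T")
    cohort_flags = FilterFlagSet()
    cohort_flags.add("hwe", key)
    excluded, soft = reciprocal_harmonize(cohort_flags, FilterFlagSet(), None, [key])
    assert key not in excluded
    assert soft[key] == {"hwe"}


def test_clean_variant_untouched():
    key = VariantKey("1", 100, "A", "T")
    excluded, soft = reciprocal_harmonize(FilterFlagSet(), FilterFlagSet(), None, [key])
    assert excluded == set() and soft == {}


def test_lcr_membership_is_reciprocal():
    inside = VariantKey("1", 151, "A", "T")  # 0-based 150 in [140, 160)
    outside = VariantKey("1", 500, "A", "T")
    lcr = MaskTrack([GenomicInterval("1", 140, 160)])
    excluded, _ = reciprocal_harmonize(
        FilterFlagSet(), FilterFlagSet(), lcr, [inside, outside]
    )
    assert inside in excluded and outside not in excluded


def test_lcr_indel_span_intersects():
    # ref spans pos..pos+len(ref); a deletion reaching into the mask is caught
    edge = VariantKey("1", 138, "AAAA", "A")  # 0-based span [137, 141) hits 140
    lcr = MaskTrack([GenomicInterval("1", 140, 160)])
    excluded, _ = reciprocal_harmonize(FilterFlagSet(), FilterFlagSet(), lcr, [edge])
    assert edge in excluded


def test_filter_order_independence():
    # permutation invariance: merged exclusion identical either way round
    k1, k2 = VariantKey("1", 100, "A", "T"), VariantKey("1", 200, "G", "C")
    f1, f2 = FilterFlagSet(), FilterFlagSet()
    f1.add("sor", k1)
    f2.add("missing", k2)
    f2.add("hwe", k1)
    e_a, s_a = reciprocal_harmonize(f1, f2, None, [k1, k2])
    e_b, s_b = reciprocal_harmonize(f2, f1, None, [k1, k2])
    assert e_a == e_b and s_a == s_b


@settings(max_examples=50, deadline=None)
@given(st.data())
def test_harmonize_idempotent_and_reciprocal_fuzz(data):
    keys = [VariantKey("1", 100 + 10 * i, "A", "T") for i in range(6)]
    all_flags = sorted(HARD_FLAGS | SOFT_FLAGS)
    fa, fb = FilterFlagSet(), FilterFlagSet()
    for f, tag in ((fa, "a"), (fb, "b")):
        for name in data.draw(
            st.lists(st.sampled_from(all_flags), max_size=4), label=tag
        ):
            f.add(name, data.draw(st.sampled_from(keys), label=f"{tag}-{name}"))
    e1, s1 = reciprocal_harmonize(fa, fb, None, keys)
    e2, s2 = reciprocal_harmonize(fa, fb, None, keys)
    assert e1 == e2 and s1 == s2  # deterministic / idempotent
    # reciprocity: exclusion is the same set regardless of which side flagged
    assert e1 == (fa.hard_excluded() | fb.hard_excluded())
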
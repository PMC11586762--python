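"""Collapsed-marker effect sizes, simulated control scores, replication
permutation testing, and simulation-based power.

Each individual is collapsed to a single marker over the unit's qualifying
variants: 0 = no variant, 1 = heterozygous variants only, 2 = at least one
homozygous variant.  The odds ratio comes from a logistic regression of
disease status on that score, falling back to Firth's penalized likelihood
under separation; with binary scores this reduces to the 2x2 cross-product
odds ratio.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
import statsmodels.api as sm

from .keys import VariantKey
from .types import MISSING, AncestryLabel, AggregationUnit, CohortGenotypeMatrix, PopulationVariantStats
from .engine import _sample_hypergeom, _unit_variant_stats

logger = logging.getLogger(__name__)

__all__ = [
    "CollapsedScore",
    "EffectEstimate",
    "collapse_genotype_scores",
    "ControlScoreSimulation",
    "simulate_control_scores",
    "estimate_odds_ratio",
    "replication_permutation_test",
    "power_by_simulation",
]


@dataclass(frozen=True)
class CollapsedScore:
    sample_id: str
    score: int  # 0, 1 or 2


@dataclass
class EffectEstimate:
    unit_id: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int
    method: str  # "logistic" or "firth"


def collapse_genotype_scores(
    cohort: CohortGenotypeMatrix,
    unit: AggregationUnit,
    qualifying: set[VariantKey],
) -> list[CollapsedScore]:
    """Per-sample collapsed marker; missing genotypes count as non-carrier."""
    rows = [
        cohort.variant_index(k)
        for k in sorted(unit.member_keys & qualifying, key=lambda k: k.packed)
        if k in cohort._index
    ]
    if not rows:
        return [CollapsedScore(s, 0) for s in cohort.samples]
    d = cohort.dosage[rows, :].astype(np.int64)
    d = np.where(d == MISSING, 0, d)
    has_hom = (d == 2).any(axis=0)
    has_het = (d == 1).any(axis=0)
    scores = np.where(has_hom, 2, np.where(has_het, 1, 0))
    return [CollapsedScore(s, int(v)) for s, v in zip(cohort.samples, scores)]


@dataclass
class ControlScoreSimulation:
    """Per-iteration carrier/homozygote counts among simulated controls."""

    n_controls: int
    iterations: int
    carrier_counts: np.ndarray  # individuals with score >= 1, per iteration
    hom_counts: np.ndarray  # individuals with score 2, per iteration

    def carrier_estimate(self, summary: str = "upper_quartile") -> float:
        """Conservative control carrier count: 'mean' or 'upper_quartile'."""
        if summary == "mean":
            return float(self.carrier_counts.mean())
        if summary == "upper_quartile":
            return float(np.percentile(self.carrier_counts, 75))
        raise ValueError(f"unknown summary {summary!r}")

    def mean_scores(self) -> tuple[float, float]:
        return float(self.carrier_counts.mean()), float(self.hom_counts.mean())


def simulate_control_scores(
    db: Mapping[VariantKey, PopulationVariantStats],
    unit: AggregationUnit,
    ancestry: AncestryLabel,
    n_controls: int,
    iterations: int = 10_000,
    seed: int | None = 0,
) -> ControlScoreSimulation:
    """Simulate collapsed scores for a control cohort.

    Per iteration, each variant's sampled alleles are placed uniformly
    without replacement into the cohort's 2*n_controls allele slots;
    an individual's two slots per variant determine het/hom carriage.
    """
    rng = np.random.default_rng(seed)
    pairs = _unit_variant_stats(db, unit.member_keys, ancestry)
    slots = 2 * n_controls
    carrier = np.zeros(iterations, dtype=np.int64)
    hom = np.zeros(iterations, dtype=np.int64)
    if not pairs:
        return ControlScoreSimulation(n_controls, iterations, carrier, hom)
    counts = [
        _sample_hypergeom(rng, ac, an, slots, iterations) for ac, an in pairs
    ]
    for i in range(iterations):
        het_any = np.zeros(n_controls, dtype=bool)
        hom_any = np.zeros(n_controls, dtype=bool)
        for v in range(len(pairs)):
            k = int(counts[v][i])
            if k == 0:
                continue
            chosen = rng.choice(slots, size=k, replace=False)
            individuals = chosen // 2
            uniq, per = np.unique(individuals, return_counts=True)
            hom_any[uniq[per == 2]] = True
            het_any[uniq[per == 1]] = True
        carrier[i] = int((het_any | hom_any).sum())
        hom[i] = int(hom_any.sum())
    return ControlScoreSimulation(n_controls, iterations, carrier, hom)


def _firth_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8):
    """Firth's bias-reduced logistic regression (Jeffreys prior penalty)."""
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        XtW = X.T * w
        info = XtW @ X
        info_inv = np.linalg.inv(info)
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * w  # hat diagonal
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1 - mu)
    cov = np.linalg.inv((X.T * w) @ X)
    return beta, cov


def estimate_odds_ratio(
    case_scores: Sequence[CollapsedScore] | Sequence[int],
    control_scores: Sequence[CollapsedScore] | Sequence[int],
    unit_id: str = "",
) -> EffectEstimate:
    """Logistic-regression odds ratio per unit score increment, Wald 95% CI.

    Complete separation (or non-convergence) falls back to Firth's
    penalized fit, which always yields a finite estimate and CI.
    """
    def _values(scores):
        return np.array(
            [s.score if isinstance(s, CollapsedScore) else int(s) for s in scores],
            dtype=float,
        )

    x_case = _values(case_scores)
    x_ctrl = _values(control_scores)
    if x_case.size == 0 or x_ctrl.size == 0:
        raise ValueError("both groups must be non-empty")
    if x_case.max(initial=0) == 0 and x_ctrl.max(initial=0) == 0:
        raise ValueError("all scores are zero in both groups; OR undefined")
    x = np.concatenate([x_case, x_ctrl])
    y = np.concatenate([np.ones(x_case.size), np.zeros(x_ctrl.size)])
    X = sm.add_constant(x)
    method = "logistic"
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation warnings precede the Firth fallback
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        beta, se = fit.params[1], fit.bse[1]
        if not (np.isfinite(beta) and np.isfinite(se)) or se > 50:
            raise ValueError("unstable fit")
    except Exception:
        beta_vec, cov = _firth_logistic(X, y)
        beta, se = beta_vec[1], float(np.sqrt(cov[1, 1]))
        method = "firth"
    z = stats.norm.ppf(0.975)
    return EffectEstimate(
        unit_id=unit_id,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        n_cases=int(x_case.size),
        n_controls=int(x_ctrl.size),
        method=method,
    )


def replication_permutation_test(
    case_allele_counts: Sequence[int],
    control_allele_counts: Sequence[int],
    n_perm: int = 100_000,
    seed: int | None = 0,
) -> float:
    """Label-permutation p for excess qualifying alleles in cases.

    The statistic is the total qualifying allele count among cases; the
    null permutes case/control labels over the pooled individuals.
    Implemented by multivariate hypergeometric resampling over the
    distinct per-individual count values, which is exactly equivalent to
    individual-level label permutation.
    """
    if n_perm < 1_000:
        logger.warning("n_perm=%d is small; permutation p will be coarse", n_perm)
    cases = np.asarray(case_allele_counts, dtype=np.int64)
    controls = np.asarray(control_allele_counts, dtype=np.int64)
    observed = int(cases.sum())
    pooled = np.concatenate([cases, controls])
    if pooled.sum() == 0:
        return 1.0
    values, colors = np.unique(pooled, return_counts=True)
    rng = np.random.default_rng(seed)
    picks = rng.multivariate_hypergeometric(colors, cases.size, size=n_perm)
    stats_perm = picks @ values
    return float(((stats_perm >= observed).sum() + 1) / (n_perm + 1))


def power_by_simulation(
    carrier_af: float,
    odds_ratio: float,
    n_cases_grid: Iterable[int],
    n_controls: int = 100_000,
    alpha: float = 2.5e-6,
    reps: int = 200,
    seed: int | None = 0,
) -> tuple[dict[int, float], int | None]:
    """Simulated power of a two-sided Fisher allele test over a case-size grid.

    Allele counts are drawn binomially (large-population approximation);
    the case allele frequency is the control frequency shifted to the
    target odds ratio.  Returns per-n power and the smallest grid n whose
    power reaches 0.8 (None if never reached).
    """
    if not (0 < carrier_af < 1):
        raise ValueError("carrier_af must be in (0, 1)")
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    rng = np.random.default_rng(seed)
    odds_case = odds_ratio * carrier_af / (1 - carrier_af)
    af_case = odds_case / (1 + odds_case)
    power: dict[int, float] = {}
    minimal_n: int | None = None
    for n in sorted(set(int(x) for x in n_cases_grid)):
        rejections = 0
        for _ in range(reps):
            a = int(rng.binomial(2 * n, af_case))
            b = int(rng.binomial(2 * n_controls, carrier_af))
            table = [[a, 2 * n - a], [b, 2 * n_controls - b]]
            _, p = stats.fisher_exact(table, alternative="two-sided")
            if p < alpha:
                rejections += 1
        power[n] = rejections / reps
        if minimal_n is None and power[n] >= 0.8:
            minimal_n = n
    return power, minimal_n
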
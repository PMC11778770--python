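"""Validation machinery for the sampling approach: sample-vs-population
comparison tests, fixed-p sensitivity analyses, and Monte-Carlo experiments
for the type-I error rate and confidence-interval coverage.

The central check mirrors how the tool was field-tested: treat each clinic or
country cohort as a finite population, size a random sample from its own
suppression rate at a +/-5-point precision, draw the sample with a uniform
RNG, and test whether the sample's ART% and VS% differ from the rest of the
population (chi-squared, or Fisher's exact test when expected cells are
small). Under random sampling about 1 comparison in 20 should reach p < 0.05
by chance alone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import ClinicPopulation, DomainError
from .continuum import ContinuumEstimate, estimate_continuum, wald_ci
from .sample_size import SampleSizeResult, required_sample_size
from .sampling import SamplePlan, uniform_random_sample
from .synthgen import SyntheticConfig, generate_population

ComparisonMode = Literal["vs_remainder", "vs_total"]

#: Expected-cell threshold below which the auto rule switches to Fisher.
FISHER_EXPECTED_CELL_MINIMUM = 5.0


class DegenerateComparisonError(DomainError):
    """The required sample is the whole population: no remainder to compare."""


@dataclass(frozen=True)
class ComparisonResult:
    """A 2x2 sample-vs-reference test for one continuum endpoint."""

    endpoint: str
    table: tuple[tuple[int, int], tuple[int, int]]  # rows: (sample, reference)
    test_used: Literal["chi_squared", "fisher_exact"]
    statistic: Optional[float]
    p_value: float
    sample_pct: float
    reference_pct: float
    comparison_mode: ComparisonMode = "vs_remainder"

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise DomainError("p-value outside [0, 1]")


def _expected_cells(table: np.ndarray) -> np.ndarray:
    total = table.sum()
    return np.outer(table.sum(axis=1), table.sum(axis=0)) / total


def compare_proportions(
    sample_counts: tuple[int, int],
    reference_counts: tuple[int, int],
    method: Literal["auto", "chi_squared", "fisher"] = "auto",
    endpoint: str = "",
    comparison_mode: ComparisonMode = "vs_remainder",
) -> ComparisonResult:
    """Test two (successes, n) groups for a difference in proportion.

    Auto mode uses the Pearson chi-squared test without continuity
    correction, switching to the two-sided Fisher exact test (sum of
    hypergeometric probabilities no larger than the observed table's) when
    any expected cell is below 5.
    """
    s_succ, s_n = sample_counts
    r_succ, r_n = reference_counts
    if s_n <= 0 or r_n <= 0:
        raise DomainError("both groups must be nonempty")
    if not (0 <= s_succ <= s_n and 0 <= r_succ <= r_n):
        raise DomainError("successes must lie in [0, n] for each group")
    table = np.array([[s_succ, s_n - s_succ], [r_succ, r_n - r_succ]], dtype=np.int64)

    if method == "auto":
        method = ("fisher" if (_expected_cells(table) < FISHER_EXPECTED_CELL_MINIMUM).any()
                  else "chi_squared")

    if method == "fisher":
        _, p = stats.fisher_exact(table, alternative="two-sided")
        test_used, statistic = "fisher_exact", None
    elif method == "chi_squared":
        if (table.sum(axis=0) == 0).any():
            # A zero column margin means both proportions are identical
            # (both 0% or both 100%): no association by construction.
            statistic, p = 0.0, 1.0
        else:
            res = stats.chi2_contingency(table, correction=False)
            statistic, p = float(res.statistic), float(res.pvalue)
        test_used = "chi_squared"
    else:
        raise DomainError(f"unknown method: {method!r}")

    return ComparisonResult(
        endpoint=endpoint,
        table=((int(table[0, 0]), int(table[0, 1])),
               (int(table[1, 0]), int(table[1, 1]))),
        test_used=test_used,
        statistic=statistic,
        p_value=float(min(1.0, p)),
        sample_pct=100.0 * s_succ / s_n,
        reference_pct=100.0 * r_succ / r_n,
        comparison_mode=comparison_mode,
    )


@dataclass(frozen=True)
class ExperimentResult:
    """One full sample-vs-population validation run, kept for audit."""

    population_label: str
    size_result: SampleSizeResult
    plan: SamplePlan
    population_estimate: ContinuumEstimate
    sample_estimate: ContinuumEstimate
    comparisons: dict[str, ComparisonResult]
    mode: ComparisonMode


def sample_vs_population_experiment(
    pop: ClinicPopulation,
    e: float,
    seed: int,
    mode: ComparisonMode = "vs_remainder",
    p_override: Optional[float] = None,
    method: Literal["auto", "chi_squared", "fisher"] = "auto",
) -> ExperimentResult:
    """Size, draw and test one random sample against its population.

    The sample size comes from the population's own realized suppression
    proportion (or ``p_override`` for fixed-p sensitivity runs) at precision
    ``e``. The reference group is the non-sampled remainder by default —
    giving two independent groups, as a chi-squared test assumes — or the
    total population in ``vs_total`` mode, which mirrors reporting the sample
    against the full cohort figure.
    """
    N = len(pop)
    pop_est = estimate_continuum(pop)
    p = pop_est.pct_vs / 100.0 if p_override is None else p_override
    size_result = required_sample_size(N, p, e)
    n = size_result.n_required
    if mode == "vs_remainder" and n >= N:
        raise DegenerateComparisonError(
            f"required n={n} leaves no remainder in a population of {N}")

    plan = uniform_random_sample(pop.ids, n, seed)
    sample_pop = pop.subset(plan.selected_ids, label=f"{pop.label}:sample")
    sample_est = estimate_continuum(sample_pop)

    if mode == "vs_remainder":
        selected = set(plan.selected_ids)
        remainder = pop.subset([i for i in pop.ids if i not in selected],
                               label=f"{pop.label}:remainder")
        ref_est = estimate_continuum(remainder)
    else:
        ref_est = pop_est

    comparisons = {
        "ART": compare_proportions(
            (sample_est.n_art, sample_est.n_in_care),
            (ref_est.n_art, ref_est.n_in_care),
            method=method, endpoint="ART", comparison_mode=mode),
        "VS": compare_proportions(
            (sample_est.n_vs, sample_est.n_in_care),
            (ref_est.n_vs, ref_est.n_in_care),
            method=method, endpoint="VS", comparison_mode=mode),
    }
    return ExperimentResult(
        population_label=pop.label,
        size_result=size_result,
        plan=plan,
        population_estimate=pop_est,
        sample_estimate=sample_est,
        comparisons=comparisons,
        mode=mode,
    )


def sensitivity_analysis(
    pops: Sequence[ClinicPopulation],
    fixed_p_values: Sequence[float] = (0.71, 0.80, 0.90),
    seed: int = 0,
    e: float = 0.05,
    alpha: float = 0.05,
    mode: ComparisonMode = "vs_remainder",
) -> pd.DataFrame:
    """Rerun the sample-vs-population experiment for every population at
    each fixed anticipated suppression rate, instead of the derived estimate.

    Lower fixed rates sit closer to 50% and therefore demand larger samples.
    Returns one row per population x fixed p: sample size, estimates, test
    used, p-value and significance at ``alpha``.
    """
    if not pops:
        raise DomainError("need at least one population")
    seeds = np.random.SeedSequence(seed).generate_state(len(pops) * len(fixed_p_values))
    rows = []
    i = 0
    for pop in pops:
        for p_fixed in fixed_p_values:
            res = sample_vs_population_experiment(
                pop, e, seed=int(seeds[i] & 0x7FFFFFFF), mode=mode,
                p_override=p_fixed)
            i += 1
            vs = res.comparisons["VS"]
            rows.append({
                "population": pop.label,
                "N": len(pop),
                "fixed_p": p_fixed,
                "n_required": res.size_result.n_required,
                "sample_pct_vs": vs.sample_pct,
                "reference_pct_vs": vs.reference_pct,
                "test_used": vs.test_used,
                "p_value": vs.p_value,
                "significant": vs.p_value < alpha,
            })
    return pd.DataFrame(rows)


def type1_error_experiment(
    config: SyntheticConfig,
    n_populations: int,
    seed: int,
    e: float = 0.05,
    alpha: float = 0.05,
) -> float:
    """Empirical false-positive rate of the sample-vs-remainder comparison.

    Generates independent synthetic populations from one configuration, runs
    the full size-draw-test pipeline in each, and returns the fraction of
    suppression-endpoint comparisons with p < ``alpha``. Because sample and
    remainder always come from the same population, every rejection is a
    false positive; the rate should sit near ``alpha`` (about 1 in 20 at
    0.05), modulo the slight conservatism of exact tests.
    """
    if n_populations < 1:
        raise DomainError("n_populations must be >= 1")
    if not 0.0 <= alpha <= 1.0:
        raise DomainError("alpha must be in [0, 1]")
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_populations)
    rejections = 0
    for i in range(n_populations):
        cfg = replace(config, seed=int(seeds[2 * i] & 0x7FFFFFFF))
        pop = generate_population(cfg)
        res = sample_vs_population_experiment(
            pop, e, seed=int(seeds[2 * i + 1] & 0x7FFFFFFF), mode="vs_remainder")
        if res.comparisons["VS"].p_value < alpha:
            rejections += 1
    return rejections / n_populations


def ci_coverage_experiment(
    config: SyntheticConfig,
    n_populations: int,
    seed: int,
    e: float = 0.05,
    confidence: float = 0.95,
) -> float:
    """Empirical coverage of the sample Wald CI for the population VS rate.

    For each replicate: generate a population, size the sample from the
    population's own realized suppression proportion at precision ``e``,
    draw it, and check whether the sample's Wald interval contains the
    realized finite-population proportion. Returns the covered fraction,
    which should approximate the nominal ``confidence`` when the sampling
    fraction is small (the plain Wald width carries no finite-population
    correction, so at large sampling fractions coverage runs high).
    """
    if n_populations < 1:
        raise DomainError("n_populations must be >= 1")
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_populations)
    covered = 0
    for i in range(n_populations):
        cfg = replace(config, seed=int(seeds[2 * i] & 0x7FFFFFFF))
        pop = generate_population(cfg)
        pop_est = estimate_continuum(pop)
        size_result = required_sample_size(len(pop), pop_est.pct_vs / 100.0, e)
        plan = uniform_random_sample(pop.ids, size_result.n_required,
                                     int(seeds[2 * i + 1] & 0x7FFFFFFF))
        sample_est = estimate_continuum(pop.subset(plan.selected_ids))
        lo, hi = wald_ci(sample_est.n_vs, sample_est.n_in_care, confidence)
        if lo <= pop_est.pct_vs <= hi:
            covered += 1
    return covered / n_populations
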
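"""Sample-vs-population comparison tests and Monte-Carlo experiments."""

import itertools

import numpy as np
import pytest

from estihiv import (
    DegenerateComparisonError,
    DomainError,
    SyntheticConfig,
    compare_proportions,
    generate_population,
    sample_vs_population_experiment,
    sensitivity_analysis,
    type1_error_experiment,
)

from oracles import fisher_two_sided_enumeration, two_proportion_z_squared


class TestCompareProportions:
    def test_fisher_matches_enumeration_example(self):
        res = compare_proportions((3, 4), (1, 4), method="fisher")
        assert res.p_value == pytest.approx(0.4857, abs=5e-5)
        assert res.test_used == "fisher_exact"
        assert res.statistic is None

    def test_identical_proportions_give_null_chi_squared(self):
        res = compare_proportions((50, 100), (50, 100), method="chi_squared")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_auto_switches_to_fisher_on_small_expected_cells(self):
        res = compare_proportions((9, 10), (10, 10), method="auto")
        assert res.test_used == "fisher_exact"

    def test_auto_uses_chi_squared_on_large_cells(self):
        res = compare_proportions((80, 100), (150, 200), method="auto")
        assert res.test_used == "chi_squared"

    def test_chi_squared_equals_squared_z(self):
        for (x1, n1, x2, n2) in [(80, 100, 150, 200), (30, 60, 45, 70),
                                 (5, 50, 40, 50), (120, 141, 300, 359)]:
            res = compare_proportions((x1, n1), (x2, n2), method="chi_squared")
            assert res.statistic == pytest.approx(
                two_proportion_z_squared(x1, n1, x2, n2), abs=1e-9)

    def test_fisher_matches_enumeration_on_small_tables(self):
        for n1, n2 in [(5, 5), (8, 6), (10, 10)]:
            for x1, x2 in itertools.product(range(n1 + 1), range(n2 + 1)):
                res = compare_proportions((x1, n1), (x2, n2), method="fisher")
                oracle = fisher_two_sided_enumeration(x1, n1 - x1, x2, n2 - x2)
                assert res.p_value == pytest.approx(oracle, abs=1e-9), (x1, x2)

    def test_zero_size_group_rejected(self):
        with pytest.raises(DomainError):
            compare_proportions((0, 0), (5, 10))

    def test_zero_column_margin_is_no_association(self):
        res = compare_proportions((10, 10), (8, 8), method="chi_squared")
        assert res.p_value == 1.0


def _pop(N=400, p_vs=0.85, seed=11, **kw):
    kw.setdefault("label", f"pop{seed}")
    return generate_population(SyntheticConfig(N=N, p_vs=p_vs, p_art=0.95,
                                               seed=seed, **kw))


class TestSampleVsPopulationExperiment:
    def test_reproducible_and_audited(self):
        pop = _pop()
        a = sample_vs_population_experiment(pop, 0.05, seed=3)
        b = sample_vs_population_experiment(pop, 0.05, seed=3)
        assert a.plan.selected_ids == b.plan.selected_ids
        assert a.comparisons["VS"].p_value == b.comparisons["VS"].p_value
        assert a.size_result.n_required == a.plan.n

    def test_worked_scale_example(self):
        """A 104-person population at ~88.5% suppression needs a sample of
        63, leaving a remainder to compare against."""
        pop = _pop(N=104, p_vs=0.885, seed=2, exact_counts=True, p_missing_vl=0.0)
        res = sample_vs_population_experiment(pop, 0.05, seed=5)
        assert res.size_result.n_required == 63
        assert set(res.comparisons) == {"ART", "VS"}
        remainder_n = res.comparisons["VS"].table[1][0] + res.comparisons["VS"].table[1][1]
        assert remainder_n == 104 - 63

    def test_no_remainder_is_degenerate(self):
        pop = _pop(N=10, p_vs=0.5)
        with pytest.raises(DegenerateComparisonError):
            sample_vs_population_experiment(pop, 0.05, seed=1, mode="vs_remainder")

    def test_whole_population_vs_total_is_self_comparison(self):
        pop = _pop(N=10, p_vs=0.5)
        res = sample_vs_population_experiment(pop, 0.05, seed=1, mode="vs_total")
        cmp = res.comparisons["VS"]
        assert cmp.sample_pct == cmp.reference_pct
        assert cmp.p_value == pytest.approx(1.0)

    def test_sample_estimates_unbiased_across_seeds(self):
        pop = _pop(N=2000, p_vs=0.85, seed=21)
        from estihiv import estimate_continuum
        true_pct = estimate_continuum(pop).pct_vs
        diffs = [sample_vs_population_experiment(pop, 0.05, seed=s)
                 .sample_estimate.pct_vs - true_pct for s in range(200)]
        assert abs(float(np.mean(diffs))) < 0.5  # percentage points


class TestSensitivityAnalysis:
    def test_lower_fixed_p_needs_larger_sample(self):
        pops = [_pop(N=1000, seed=s) for s in (1, 2)]
        table = sensitivity_analysis(pops, seed=4)
        for _, group in table.groupby("population"):
            by_p = group.set_index("fixed_p")["n_required"]
            assert by_p[0.71] > by_p[0.80] > by_p[0.90]

    def test_row_count(self):
        pops = [_pop(N=500, seed=s) for s in range(3)]
        table = sensitivity_analysis(pops, fixed_p_values=(0.71, 0.80, 0.90), seed=0)
        assert len(table) == 9

    def test_fixed_p_equal_to_derived_matches_primary(self):
        pop = _pop(N=800, seed=6)
        from estihiv import estimate_continuum, required_sample_size
        derived = estimate_continuum(pop).pct_vs / 100.0
        table = sensitivity_analysis([pop], fixed_p_values=(derived,), seed=0)
        assert (table["n_required"] ==
                required_sample_size(len(pop), derived, 0.05).n_required).all()


class TestType1ErrorExperiment:
    def test_alpha_extremes(self):
        cfg = SyntheticConfig(N=300, p_vs=0.85, p_art=0.95, seed=0)
        assert type1_error_experiment(cfg, 5, seed=1, alpha=1.0) == 1.0
        assert type1_error_experiment(cfg, 5, seed=1, alpha=0.0) == 0.0

    def test_small_run_is_deterministic(self):
        cfg = SyntheticConfig(N=300, p_vs=0.85, p_art=0.95, seed=0)
        a = type1_error_experiment(cfg, 40, seed=9)
        b = type1_error_experiment(cfg, 40, seed=9)
        assert a == b
        assert 0.0 <= a <= 0.25  # loose sanity bound at 40 replicates
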
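"""Classification rules, Wald intervals, continuum estimates, stratification."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from estihiv import (
    DomainError,
    EmptyPopulationError,
    Gender,
    TransmissionGroup,
    classify_art,
    classify_vs,
    estimate_continuum,
    stratify_continuum,
    wald_ci,
)

from conftest import make_population, make_record
from oracles import wald_ci_direct


class TestClassifyVs:
    def test_below_threshold_suppressed(self):
        assert classify_vs(make_record(vl=150), threshold=200)

    def test_at_threshold_not_suppressed(self):
        assert not classify_vs(make_record(vl=200), threshold=200)

    def test_missing_vl_is_failure(self):
        assert not classify_vs(make_record(vl=None), threshold=200)

    def test_dataset_500_rule(self):
        # a setting that defines suppression below 500 copies/ml
        assert classify_vs(make_record(vl=450), threshold=500)
        assert not classify_vs(make_record(vl=450), threshold=200)

    def test_lod_at_or_above_threshold_counts_below_lod_as_suppressed(self):
        assert classify_vs(make_record(vl=300), threshold=200, lod=400)
        assert not classify_vs(make_record(vl=300), threshold=200, lod=100)


class TestClassifyArt:
    @pytest.mark.parametrize("status, expected", [
        ("yes", True), ("no", False), ("unknown", False)])
    def test_yes_only(self, status, expected):
        assert classify_art(make_record(on_art=status)) is expected


class TestWaldCi:
    @pytest.mark.parametrize("p_hat_pct, n, rounded", [
        (76.7, 8852, (75.8, 77.6)),
        (97.8, 26426, (97.6, 98.0)),
        (91.5, 26426, (91.2, 91.8)),
    ])
    def test_reproduces_printed_intervals(self, p_hat_pct, n, rounded):
        lo, hi = wald_ci(p_hat_pct / 100.0 * n, n)
        assert (round(lo, 1), round(hi, 1)) == rounded

    def test_degenerate_at_full_count(self):
        assert wald_ci(20, 20) == (100.0, 100.0)
        assert wald_ci(0, 20) == (0.0, 0.0)

    def test_zero_n_rejected(self):
        with pytest.raises(DomainError):
            wald_ci(0, 0)

    def test_matches_direct_derivation_on_grid(self):
        for n in (5, 17, 63, 231, 8852):
            for count in {0, 1, n // 3, n // 2, n - 1, n}:
                ours = wald_ci(count, n)
                ref = wald_ci_direct(count, n)
                assert ours[0] == pytest.approx(ref[0], abs=1e-9)
                assert ours[1] == pytest.approx(ref[1], abs=1e-9)

    @given(count=st.integers(1, 199))
    @settings(derandomize=True, max_examples=60)
    def test_width_shrinks_with_n_and_symmetric(self, count):
        n = 200
        lo1, hi1 = wald_ci(count, n)
        lo2, hi2 = wald_ci(count * 4, n * 4)  # same p_hat, larger n
        assert hi2 - lo2 < hi1 - lo1
        p_pct = 100.0 * count / n
        if 0.0 < lo1 and hi1 < 100.0:  # symmetric unless clipped
            assert hi1 - p_pct == pytest.approx(p_pct - lo1, abs=1e-9)


class TestEstimateContinuum:
    def test_direct_counts(self, ten_person_pop):
        est = estimate_continuum(ten_person_pop)
        assert est.n_in_care == 10
        assert est.pct_art == pytest.approx(90.0)
        assert est.pct_vs == pytest.approx(70.0)
        assert est.n_missing_vl == 1

    def test_missing_vl_percentage_rounding(self):
        records = [make_record(f"p{i:03d}", vl=None if i < 24 else 50)
                   for i in range(231)]
        est = estimate_continuum(make_population(records))
        assert round(est.pct_missing_vl, 1) == 10.4

    def test_all_suppressed(self):
        pop = make_population([make_record(f"p{i}", vl=10) for i in range(8)])
        est = estimate_continuum(pop)
        assert est.pct_vs == 100.0
        assert est.vs_ci == (100.0, 100.0)

    def test_empty_population_rejected(self):
        pop = make_population([make_record("a")])
        empty = pop.subset([])
        with pytest.raises(EmptyPopulationError):
            estimate_continuum(empty)

    def test_missing_as_failure_not_above_complete_case(self, ten_person_pop):
        default = estimate_continuum(ten_person_pop)
        complete = estimate_continuum(ten_person_pop, complete_case=True)
        assert default.pct_vs <= complete.pct_vs + 1e-12


class TestStratifyContinuum:
    def _pop(self):
        records = []
        for i in range(5):  # MSM: 4 of 5 suppressed
            records.append(make_record(f"m{i}", vl=50 if i < 4 else 9000,
                                       transmission_group=TransmissionGroup.MSM))
        for i in range(5):  # IDU: 1 of 5 suppressed
            records.append(make_record(f"i{i}", vl=50 if i < 1 else 9000,
                                       transmission_group=TransmissionGroup.IDU))
        return make_population(records)

    def test_group_percentages(self):
        by_group = {e.group_label: e for e in
                    stratify_continuum(self._pop(), "transmission_group")}
        assert by_group["MSM"].pct_vs == pytest.approx(80.0)
        assert by_group["IDU"].pct_vs == pytest.approx(20.0)

    def test_denominators_partition_overall(self):
        pop = self._pop()
        strata = stratify_continuum(pop, "transmission_group")
        assert sum(e.n_in_care for e in strata) == len(pop)

    def test_single_group_matches_overall(self):
        pop = make_population([make_record(f"p{i}", vl=50) for i in range(6)])
        (only,) = stratify_continuum(pop, "gender")
        overall = estimate_continuum(pop)
        assert only.pct_vs == overall.pct_vs
        assert only.n_in_care == overall.n_in_care

    def test_small_groups_masked(self):
        records = [make_record(f"m{i}", vl=50) for i in range(6)]
        records.append(make_record("f0", vl=50, gender=Gender.FEMALE))
        strata = {e.group_label: e for e in stratify_continuum(
            make_population(records), "gender", masking_minimum=5)}
        assert not strata["male"].masked
        assert strata["female"].masked
        assert math.isnan(strata["female"].pct_vs)
        assert strata["female"].n_in_care == 1  # counts survive masking
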
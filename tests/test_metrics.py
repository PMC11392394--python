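import numpy as np
import pandas as pd
import pytest

from helpers import make_encounter
from ventalloc.cohort import cohort_to_frame
from ventalloc.metrics import (
    age_adjusted_rate,
    age_strata_masks,
    allocation_rate,
    baseline_life_years,
    baseline_survival,
    build_report,
    life_years_saved,
    lives_saved,
    replicate_age_adjusted_survival,
    survival_rate,
)
from ventalloc.simulator import AllocationResult, SimulationConfig, run_simulation


def toy_result(allocation, survived, life_expectancy=None, ages=None, races=None, capacity=0.5):
    allocation = np.asarray(allocation, dtype=bool)
    n = allocation.shape[1]
    cohort = cohort_to_frame(
        [
            make_encounter(
                encounter_id=f"t{i}",
                age=int(ages[i]) if ages is not None else 50,
                race_ethnicity=races[i] if races is not None else "white_nh",
                survived=bool(survived[i]),
                life_expectancy=None if life_expectancy is None else float(life_expectancy[i]),
            )
            for i in range(n)
        ]
    )
    return AllocationResult(
        protocol="lottery",
        capacity=capacity,
        allocation=allocation,
        survived=np.asarray(survived, dtype=bool),
        life_expectancy=None if life_expectancy is None else np.asarray(life_expectancy, float),
        cohort=cohort,
    )


class TestSurvivalRate:
    def test_all_allocated_all_survive(self):
        res = toy_result([[1, 1, 1, 1]], [1, 1, 1, 1])
        assert survival_rate(res).mean == 1.0

    def test_hand_computed_single_replicate(self):
        # 4 patients, 2 allocated, 1 of those survives -> 0.25
        res = toy_result([[1, 1, 0, 0]], [1, 0, 1, 0])
        assert survival_rate(res).mean == 0.25

    def test_unallocated_survivor_counts_as_death(self):
        res = toy_result([[0, 0]], [1, 1])
        assert survival_rate(res).mean == 0.0

    def test_empty_subgroup_is_nan_marker(self):
        res = toy_result([[1, 0]], [1, 0])
        summary = survival_rate(res, mask=np.zeros(2, dtype=bool))
        assert not summary.defined
        assert np.isnan(summary.mean)

    def test_decomposition_over_subgroups(self, small_cohort):
        config = SimulationConfig("age", 0.5, replicates=20, seed=2)
        result = run_simulation(small_cohort, config)
        race = result.cohort["race_ethnicity"].to_numpy()
        overall = survival_rate(result)
        total = np.zeros_like(overall.per_replicate)
        for r in np.unique(race):
            sub = survival_rate(result, mask=race == r)
            total += sub.per_replicate * sub.n
        np.testing.assert_allclose(total / len(small_cohort), overall.per_replicate)


class TestAllocationRate:
    def test_full_allocation(self):
        res = toy_result([[1, 1, 1]], [0, 0, 0])
        assert allocation_rate(res).mean == 1.0

    def test_lottery_subgroups_near_capacity(self, small_cohort):
        config = SimulationConfig("lottery", 0.5, replicates=200, seed=4)
        result = run_simulation(small_cohort, config)
        race = result.cohort["race_ethnicity"].to_numpy()
        for r in ("white_nh", "black_nh"):
            rate = allocation_rate(result, mask=race == r)
            assert abs(rate.mean - 0.5) < 0.03


class TestLivesSaved:
    def test_zero_when_survival_equals_expected(self):
        # Baseline 0.5; capacity 0.5 -> expected 0.25; simulated exactly 0.25.
        res = toy_result([[1, 1, 0, 0]], [1, 0, 1, 0], capacity=0.5)
        assert baseline_survival(res) == 0.5
        assert lives_saved(res).mean == pytest.approx(0.0)

    def test_lottery_unbiased(self, small_cohort):
        config = SimulationConfig("lottery", 0.5, replicates=300, seed=6)
        result = run_simulation(small_cohort, config)
        ls = lives_saved(result)
        se = np.std(ls.per_replicate, ddof=1) / np.sqrt(len(ls.per_replicate))
        assert abs(ls.mean) < 2 * se

    def test_informative_protocol_beats_lottery(self, default_cohort):
        surv = {}
        for protocol in ("pure_sofa", "lottery"):
            config = SimulationConfig(protocol, 0.5, replicates=50, seed=8)
            surv[protocol] = lives_saved(run_simulation(default_cohort, config)).mean
        assert surv["pure_sofa"] > surv["lottery"]

    def test_per_1000_scaling(self):
        res = toy_result([[1, 1, 0, 0]], [1, 1, 1, 0], capacity=0.5)
        ls = lives_saved(res)
        assert ls.scaled(1000).mean == pytest.approx(ls.mean * 1000)


class TestLifeYearsSaved:
    def test_nobody_survives(self):
        res = toy_result([[1, 1]], [0, 0], life_expectancy=[10.0, 20.0], capacity=0.5)
        lys = life_years_saved(res)
        assert lys.mean == pytest.approx(0.0)  # baseline LY is 0 too

    def test_matches_hand_computation(self):
        # Baseline LY = (30 + 0*10)/2 = 15; sim realises 30/2 = 15; capacity .5
        res = toy_result([[1, 0]], [1, 0], life_expectancy=[30.0, 10.0], capacity=0.5)
        assert baseline_life_years(res) == 15.0
        assert life_years_saved(res).mean == pytest.approx(15.0 - 15.0 * 0.5)

    def test_missing_annotation_raises(self):
        res = toy_result([[1, 0]], [1, 0])
        with pytest.raises(ValueError, match="annotate"):
            life_years_saved(res)

    def test_lottery_unbiased(self, small_cohort):
        config = SimulationConfig("lottery", 0.5, replicates=300, seed=9)
        result = run_simulation(small_cohort, config)
        lys = life_years_saved(result)
        se = np.std(lys.per_replicate, ddof=1) / np.sqrt(len(lys.per_replicate))
        assert abs(lys.mean) < 2 * se


class TestAgeAdjustedRate:
    def test_equal_rates_invariant(self):
        rate, lo, hi = age_adjusted_rate([20, 40], [100, 200], [0.3, 0.7])
        assert rate == pytest.approx(0.2)
        assert lo < 0.2 < hi

    def test_two_strata_arithmetic(self):
        rate, _, _ = age_adjusted_rate([20, 80], [100, 100], [0.5, 0.5])
        assert rate == pytest.approx(0.5)

    def test_zero_denominator_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero denominators"):
            rate, _, _ = age_adjusted_rate([20, 0], [100, 0], [0.5, 0.5])
        assert rate == pytest.approx(0.2)

    def test_misaligned_inputs(self):
        with pytest.raises(ValueError):
            age_adjusted_rate([1, 2], [10], [0.5, 0.5])

    def test_replicate_adjusted_equals_crude_for_standard_population(self, small_cohort):
        # Standard = the cohort's own age distribution, subgroup = everyone:
        # the standardised rate is exactly the crude rate.
        config = SimulationConfig("lottery", 0.5, replicates=10, seed=12)
        result = run_simulation(small_cohort, config)
        crude = survival_rate(result)
        adjusted = replicate_age_adjusted_survival(result)
        np.testing.assert_allclose(adjusted.per_replicate, crude.per_replicate)

    def test_age_strata_masks_partition(self, small_cohort):
        ages = np.array([e.age for e in small_cohort])
        masks = age_strata_masks(ages)
        assert sum(m.sum() for m in masks) == len(ages)


class TestCIBehaviour:
    def test_ci_shrinks_with_replicates(self, small_cohort):
        widths = {}
        for reps in (50, 400):
            config = SimulationConfig("age", 0.5, replicates=reps, seed=14)
            surv = survival_rate(run_simulation(small_cohort, config))
            widths[reps] = surv.ci_high - surv.ci_low
        assert widths[400] < widths[50]


class TestBuildReport:
    def test_single_cell(self, small_cohort, tmp_path):
        config = SimulationConfig("age", 0.5, replicates=5, seed=15)
        result = run_simulation(small_cohort, config)
        tables = build_report({"age": {0.5: result}}, out_dir=tmp_path)
        sweep = tables["capacity_sweep"]
        assert len(sweep) == 1
        assert (tmp_path / "capacity_sweep.csv").exists()
        assert (tmp_path / "table3_lives_saved.csv").exists()
        surv = tables["table2_survival_allocation"]
        assert set(surv["group"]) == {"overall", "black_nh", "hispanic", "white_nh"}

    def test_row_counting(self, small_cohort):
        results = {}
        for protocol in ("lottery", "age"):
            results[protocol] = {}
            for capacity in (0.25, 0.5):
                config = SimulationConfig(protocol, capacity, replicates=3, seed=16)
                results[protocol][capacity] = run_simulation(small_cohort, config)
        tables = build_report(results)
        assert len(tables["capacity_sweep"]) == 4
        assert len(tables["table3_lives_saved"]) == 4 * 4  # 4 groups per cell

    def test_ls_lys_positively_correlated_within_protocol(self, default_cohort):
        config = SimulationConfig("age", 0.5, replicates=100, seed=18)
        result = run_simulation(default_cohort, config)
        ls = lives_saved(result).per_replicate
        lys = life_years_saved(result).per_replicate
        assert np.corrcoef(ls, lys)[0, 1] > 0
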
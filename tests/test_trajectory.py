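import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from equicea.params import CostTable, DisabilityWeightSet
from equicea.strata import AGE_BANDS, SEXES
from equicea.trajectory import (
    build_trajectory,
    discount_factor,
    haly_weight,
    value_costs,
    value_halys,
)

LUNG_DW = DisabilityWeightSet(
    diagnosis=0.469, preterminal=0.539, terminal=0.548, remission=0.315
)
NO_PYLD = np.zeros(len(AGE_BANDS))


def zero_cost_table() -> CostTable:
    zero_by_band = {(b, s): 0.0 for b in AGE_BANDS for s in SEXES}
    return CostTable(
        background_annual=dict(zero_by_band),
        last_six_months=dict(zero_by_band),
        cancer_monthly={
            "lung": {p: 0.0 for p in ("diagnosis", "remission", "preterminal", "terminal")}
        },
    )


class TestBuildTrajectory:
    def test_lung_cancer_death_at_month_11(self, lung_schedule):
        traj = build_trajectory("cancer_death", 11, lung_schedule, 600, 52.5)
        assert list(traj.phases[:5]) == ["diagnosis"] * 5
        assert list(traj.phases[5:10]) == ["preterminal"] * 5
        assert traj.phases[10] == "terminal"

    def test_early_death_applies_end_anchored_precedence(self, lung_schedule):
        traj = build_trajectory("cancer_death", 3, lung_schedule, 600, 52.5)
        assert list(traj.phases) == ["preterminal", "preterminal", "terminal"]

    def test_late_death_includes_remission_gap(self, lung_schedule):
        traj = build_trajectory("cancer_death", 20, lung_schedule, 600, 52.5)
        assert list(traj.phases[:5]) == ["diagnosis"] * 5
        assert list(traj.phases[5:14]) == ["remission"] * 9
        assert list(traj.phases[14:19]) == ["preterminal"] * 5
        assert traj.phases[19] == "terminal"

    def test_survivor_passes_through_cure(self, lung_schedule):
        traj = build_trajectory("survivor", None, lung_schedule, 100, 52.5)
        assert list(traj.phases[:5]) == ["diagnosis"] * 5
        assert all(p == "remission" for p in traj.phases[5:72])
        assert all(p == "cured" for p in traj.phases[72:])
        assert traj.n_months == 100

    def test_other_cause_death_flags_final_six_months(self, lung_schedule):
        traj = build_trajectory("other_death", 50, lung_schedule, 600, 52.5)
        assert traj.last6.sum() == 6
        assert traj.last6[-6:].all()
        assert "terminal" not in traj.phases

    def test_death_beyond_horizon_rejected(self, lung_schedule):
        with pytest.raises(ValueError, match="death month"):
            build_trajectory("cancer_death", 601, lung_schedule, 600, 52.5)

    @given(d=st.integers(min_value=1, max_value=690))
    @settings(max_examples=60, derandomize=True)
    def test_phases_partition_lived_months(self, d):
        from equicea.params import PhaseSchedule

        schedule = PhaseSchedule(
            diagnosis_months=5, preterminal_months=5, terminal_months=1,
            cure_months=72,
        )
        for outcome in ("cancer_death", "other_death"):
            traj = build_trajectory(outcome, d, schedule, 690, 52.5)
            assert traj.n_months == d
            assert (traj.phases != "").all()
            cured = np.flatnonzero(traj.phases == "cured")
            if cured.size:
                # cured slots only after the statistical-cure month
                assert cured.min() + 1 > schedule.cure_months
            if outcome == "cancer_death":
                assert traj.phases[-1] == "terminal"
                assert (traj.phases == "terminal").sum() == 1


class TestDiscounting:
    def test_zero_rate_never_discounts(self):
        assert discount_factor(240, 0.0) == 1.0

    def test_one_year_at_three_percent(self):
        assert discount_factor(12, 0.03) == pytest.approx(0.97087, abs=1e-5)

    def test_strictly_decreasing_in_time(self):
        f = discount_factor(np.arange(1, 100), 0.03)
        assert (np.diff(f) < 0).all()


class TestHalyWeight:
    def test_morbidity_envelope_for_cured_survivor(self):
        assert haly_weight("cured", LUNG_DW, 0.224) == pytest.approx(0.776)

    def test_all_switches_off_is_full_health(self):
        assert haly_weight("diagnosis", LUNG_DW, 0.3, dw_on=False, pyld_on=False) == 1.0

    def test_lung_diagnosis_weight_without_envelope(self):
        assert haly_weight("diagnosis", LUNG_DW, 0.0) == pytest.approx(0.531)


class TestValueHalys:
    def test_one_undiscounted_healthy_year_is_one_haly(self, lung_schedule):
        traj = build_trajectory("survivor", None, lung_schedule, 12, 52.5)
        value = value_halys(traj, LUNG_DW, NO_PYLD, 0.0, dw_on=False, pyld_on=False)
        assert value == pytest.approx(1.0)

    def test_hand_summed_lung_death_at_month_11(self, lung_schedule):
        traj = build_trajectory("cancer_death", 11, lung_schedule, 600, 52.5)
        value = value_halys(traj, LUNG_DW, NO_PYLD, 0.0, pyld_on=False)
        assert value == pytest.approx((5 * 0.531 + 5 * 0.461 + 1 * 0.452) / 12, abs=1e-4)

    def test_discounting_strictly_reduces_value(self, lung_schedule):
        traj = build_trajectory("survivor", None, lung_schedule, 240, 52.5)
        assert value_halys(traj, LUNG_DW, NO_PYLD, 0.03) < value_halys(
            traj, LUNG_DW, NO_PYLD, 0.0
        )

    def test_bounded_by_undiscounted_lived_years(self, lung_schedule):
        traj = build_trajectory("cancer_death", 57, lung_schedule, 600, 52.5)
        value = value_halys(traj, LUNG_DW, np.full(len(AGE_BANDS), 0.3), 0.0)
        assert 0 <= value <= 57 / 12

    @given(
        d=st.integers(min_value=1, max_value=400),
        pyld=st.floats(min_value=0.0, max_value=0.8, allow_nan=False),
        r=st.floats(min_value=0.0, max_value=0.1, allow_nan=False),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_switching_on_morbidity_never_increases_halys(self, d, pyld, r):
        from equicea.params import PhaseSchedule

        schedule = PhaseSchedule(
            diagnosis_months=5, preterminal_months=5, terminal_months=1,
            cure_months=72,
        )
        traj = build_trajectory("cancer_death", d, schedule, 600, 52.5)
        pyld_arr = np.full(len(AGE_BANDS), pyld)
        base = value_halys(traj, LUNG_DW, pyld_arr, r, dw_on=False, pyld_on=False)
        assert value_halys(traj, LUNG_DW, pyld_arr, r, dw_on=True, pyld_on=False) <= base
        assert value_halys(traj, LUNG_DW, pyld_arr, r, dw_on=False, pyld_on=True) <= base

    def test_additive_over_disjoint_month_ranges(self, lung_schedule):
        """The trajectory value equals the sum of its per-month
        contributions computed independently from the weight and
        discount primitives."""
        traj = build_trajectory("cancer_death", 30, lung_schedule, 600, 52.5)
        manual = sum(
            haly_weight(phase, LUNG_DW, 0.0) / 12 * discount_factor(t, 0.03)
            for t, phase in enumerate(traj.phases, start=1)
        )
        assert value_halys(traj, LUNG_DW, NO_PYLD, 0.03) == pytest.approx(manual)


class TestValueCosts:
    def test_direct_cost_over_full_diagnosis_phase(self, lung_schedule):
        traj = build_trajectory("cancer_death", 30, lung_schedule, 600, 52.5)
        cost = value_costs(
            traj, zero_cost_table(), "lung", "male",
            intervention_on=True, direct_monthly_cost=2500.0, annual_rate=0.0,
        )
        assert cost == pytest.approx(5 * 2500.0)

    def test_zero_tables_without_intervention_cost_nothing(self, lung_schedule):
        traj = build_trajectory("other_death", 48, lung_schedule, 600, 52.5)
        assert value_costs(traj, zero_cost_table(), "lung", "male") == 0.0

    def test_longer_survival_accrues_more_background_cost(self, lung_schedule):
        table = zero_cost_table()
        for b in AGE_BANDS:
            for s in SEXES:
                table.background_annual[(b, s)] = 3000.0
        short = build_trajectory("survivor", None, lung_schedule, 60, 52.5)
        long = build_trajectory("survivor", None, lung_schedule, 120, 52.5)
        kw = dict(cost_table=table, cancer="lung", sex="male", annual_rate=0.0)
        assert value_costs(long, **kw) > value_costs(short, **kw)

    def test_last_six_months_cost_substitutes_background(self, lung_schedule):
        table = zero_cost_table()
        for b in AGE_BANDS:
            for s in SEXES:
                table.background_annual[(b, s)] = 1200.0  # $100/month
                table.last_six_months[(b, s)] = 30000.0  # $5000/month
        traj = build_trajectory("other_death", 24, lung_schedule, 600, 52.5)
        cost = value_costs(traj, table, "lung", "female", annual_rate=0.0)
        assert cost == pytest.approx(18 * 100.0 + 6 * 5000.0)
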
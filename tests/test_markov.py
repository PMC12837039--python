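"""Cohort-engine unit tests: matrix structure, discounting, accrual rules."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crcua.markov import (
    CALIBRATED_VARIANT,
    WITH_SCREENING,
    WITHOUT_SCREENING,
    ArmParameters,
    CostSet,
    HealthState,
    ModelConfig,
    StageSplit,
    StructuralVariant,
    UtilitySet,
    accrued_totals,
    build_transition_matrix,
    discount_factor,
    discount_factors,
    run_cohort,
)


def _arm(label=WITH_SCREENING, p_early=0.67, p_progress=0.0243, p_die_early=0.0187, p_die_late=0.1476):
    return ArmParameters(
        arm_label=label,
        stage_split=StageSplit.from_early(p_early),
        p_progress=p_progress,
        p_die_early=p_die_early,
        p_die_late=p_die_late,
    )


def _config(arm_w=None, arm_wo=None, **kwargs):
    arm_w = arm_w or _arm(WITH_SCREENING)
    arm_wo = arm_wo or _arm(WITHOUT_SCREENING, p_early=0.46)
    return ModelConfig(arms={WITH_SCREENING: arm_w, WITHOUT_SCREENING: arm_wo}, **kwargs)


class TestTransitionMatrix:
    def test_early_stage_row_matches_published_probabilities(self):
        m = build_transition_matrix(_arm())
        row = m[HealthState.STAGE_I_II]
        assert row[HealthState.STAGE_I_II] == pytest.approx(0.9570, abs=5e-5)
        assert row[HealthState.STAGE_III_IV] == pytest.approx(0.0243, abs=5e-5)
        assert row[HealthState.DEAD] == pytest.approx(0.0187, abs=5e-5)

    def test_death_is_absorbing(self):
        m = build_transition_matrix(_arm())
        assert np.array_equal(m[HealthState.DEAD], [0, 0, 0, 1])

    @given(
        p_early=st.floats(0.0, 1.0),
        p_progress=st.floats(0.0, 0.5),
        p_die_early=st.floats(0.0, 0.4),
        p_die_late=st.floats(0.4, 1.0),
    )
    def test_rows_are_stochastic(self, p_early, p_progress, p_die_early, p_die_late):
        m = build_transition_matrix(
            _arm(p_early=p_early, p_progress=p_progress,
                 p_die_early=p_die_early, p_die_late=p_die_late)
        )
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
        assert (m >= 0).all()

    def test_excess_outgoing_probability_rejected(self):
        with pytest.raises(ValueError):
            _arm(p_progress=0.7, p_die_early=0.5)

    def test_mortality_ordering_enforced(self):
        with pytest.raises(ValueError):
            _arm(p_die_early=0.3, p_die_late=0.2)


class TestDiscounting:
    @pytest.mark.parametrize(
        "cycle, rate, expected",
        [(0, 0.035, 1.0), (1, 0.035, 1 / 1.035), (10, 0.0, 1.0)],
    )
    def test_delayed_convention(self, cycle, rate, expected):
        assert discount_factor(cycle, rate) == pytest.approx(expected, rel=1e-12)

    def test_from_first_cycle_convention_discounts_year_one(self):
        assert discount_factor(0, 0.035, "from_first_cycle") == pytest.approx(1 / 1.035)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(1, -0.01)
        with pytest.raises(ValueError):
            discount_factors(5, -0.01)

    def test_vector_matches_scalar(self):
        d = discount_factors(5, 0.035)
        assert d == pytest.approx([discount_factor(t, 0.035) for t in range(5)])


class TestRunCohort:
    def test_zero_horizon_accrues_nothing(self):
        trace = run_cohort(_config(horizon_cycles=0), WITH_SCREENING)
        assert trace.total_cost == 0.0 and trace.total_qaly == 0.0
        assert accrued_totals(trace) == (0.0, 0.0)

    def test_advanced_stage_only_cohort_matches_geometric_closed_form(self):
        """A cohort starting in stage III-IV with no discounting accrues
        u_late * (1 - (1-p)^H) / p QALYs (geometric series of survivors)."""
        p = 1 - 0.45 ** 0.2
        cfg = _config(
            arm_w=_arm(p_early=0.0, p_die_late=p),
            arm_wo=_arm(WITHOUT_SCREENING, p_early=0.0, p_die_late=p),
            discount_rate=0.0,
            costs=CostSet(0.0, 0.0, 0.0, 0.0),
            variant=StructuralVariant(diagnosis_timing="at_entry"),
        )
        trace = run_cohort(cfg, WITH_SCREENING)
        expected = 0.46 * (1 - (1 - p) ** 50) / p
        assert trace.total_qaly == pytest.approx(expected, rel=1e-12)

    def test_accrued_totals_resum_the_cycle_series(self, base_config):
        trace = run_cohort(base_config, WITHOUT_SCREENING)
        cost, qaly = accrued_totals(trace)
        assert cost == pytest.approx(trace.total_cost, rel=1e-15)
        assert qaly == pytest.approx(trace.total_qaly, rel=1e-15)

    def test_screening_cost_charged_to_screening_arm_only(self, base_config):
        zeroed = replace(
            base_config,
            costs=CostSet(screening_cost=0.0,
                          colonoscopy_cost=base_config.costs.colonoscopy_cost,
                          late_treatment_cost=base_config.costs.late_treatment_cost,
                          palliative_cost=base_config.costs.palliative_cost),
        )
        delta_with = (
            run_cohort(base_config, WITH_SCREENING).total_cost
            - run_cohort(zeroed, WITH_SCREENING).total_cost
        )
        delta_without = (
            run_cohort(base_config, WITHOUT_SCREENING).total_cost
            - run_cohort(zeroed, WITHOUT_SCREENING).total_cost
        )
        assert delta_with == pytest.approx(base_config.costs.screening_cost, rel=1e-9)
        assert delta_without == 0.0

    def test_zero_utilities_give_zero_qalys(self, base_config):
        cfg = replace(
            base_config,
            utilities=UtilitySet(0.0, 0.0, 0.0),
            variant=replace(base_config.variant, undiagnosed_utility_mode="stage_weighted"),
        )
        assert run_cohort(cfg, WITH_SCREENING).total_qaly == 0.0

    def test_higher_mortality_strictly_lowers_qalys(self, base_config):
        from crcua.synthetic import perturbed_fixture

        bumped = perturbed_fixture(base_config, 0.1, fields=("p_die_late",))
        for arm in (WITH_SCREENING, WITHOUT_SCREENING):
            assert (
                run_cohort(bumped, arm).total_qaly < run_cohort(base_config, arm).total_qaly
            )

    def test_discounting_strictly_lowers_both_totals(self, base_config):
        heavier = replace(base_config, discount_rate=0.05)
        for arm in (WITH_SCREENING, WITHOUT_SCREENING):
            base = run_cohort(base_config, arm)
            disc = run_cohort(heavier, arm)
            assert disc.total_cost < base.total_cost
            assert disc.total_qaly < base.total_qaly

    def test_screening_arm_gains_qalys_from_earlier_stage_detection(self, base_config):
        with_trace = run_cohort(base_config, WITH_SCREENING)
        without_trace = run_cohort(base_config, WITHOUT_SCREENING)
        assert with_trace.total_qaly > without_trace.total_qaly

    def test_trace_frame_has_one_row_per_cycle(self, base_config):
        frame = run_cohort(base_config, WITH_SCREENING).to_frame()
        assert len(frame) == base_config.horizon_cycles
        assert frame[["undiagnosed", "stage_i_ii", "stage_iii_iv", "dead"]].sum(axis=1).round(9).eq(1.0).all()


variant_strategy = st.builds(
    StructuralVariant,
    diagnosis_timing=st.sampled_from(["at_entry", "after_one_cycle"]),
    undiagnosed_utility_mode=st.sampled_from(["full_health", "stage_weighted"]),
    half_cycle_correction=st.booleans(),
    late_cost_recurrence=st.sampled_from(["once_on_entry", "every_cycle", "excluded"]),
    colonoscopy_charge=st.sampled_from(["all_diagnosed", "early_only"]),
    transition_cost_timing=st.sampled_from(["departure", "arrival"]),
    discount_convention=st.sampled_from(["delayed", "from_first_cycle"]),
)


@settings(max_examples=60, deadline=None)
@given(
    variant=variant_strategy,
    p_early=st.floats(0.05, 0.95),
    p_progress=st.floats(0.0, 0.3),
    p_die_early=st.floats(0.0, 0.3),
    p_die_late=st.floats(0.3, 0.9),
    rate=st.floats(0.0, 0.1),
)
def test_occupancy_conserved_and_death_absorbing(
    variant, p_early, p_progress, p_die_early, p_die_late, rate
):
    """Mass conservation and monotone death occupancy for random configs."""
    cfg = _config(
        arm_w=_arm(p_early=p_early, p_progress=p_progress,
                   p_die_early=p_die_early, p_die_late=p_die_late),
        arm_wo=_arm(WITHOUT_SCREENING, p_early=p_early / 2, p_progress=p_progress,
                    p_die_early=p_die_early, p_die_late=p_die_late),
        variant=variant,
        discount_rate=rate,
        horizon_cycles=30,
    )
    for arm in (WITH_SCREENING, WITHOUT_SCREENING):
        trace = run_cohort(cfg, arm)
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
        dead = trace.occupancy[:, HealthState.DEAD]
        assert (np.diff(dead) >= -1e-12).all()


def test_calibrated_default_variant_is_shipped():
    assert CALIBRATED_VARIANT == StructuralVariant()
    assert ModelConfig().variant == CALIBRATED_VARIANT


def test_base_case_reproduces_published_cohort_totals(base_config, published):
    """The calibrated variant lands within 5% of all four published
    discounted totals and reproduces the headline increments."""
    pub = published["per_patient"]
    with_trace = run_cohort(base_config, WITH_SCREENING)
    without_trace = run_cohort(base_config, WITHOUT_SCREENING)
    assert with_trace.total_cost == pytest.approx(pub["cost_with"], rel=0.05)
    assert with_trace.total_qaly == pytest.approx(pub["qaly_with"], rel=0.05)
    assert without_trace.total_cost == pytest.approx(pub["cost_without"], rel=0.05)
    assert without_trace.total_qaly == pytest.approx(pub["qaly_without"], rel=0.05)
    assert with_trace.total_cost - without_trace.total_cost == pytest.approx(
        pub["delta_cost"], rel=0.02
    )
    assert with_trace.total_qaly - without_trace.total_qaly == pytest.approx(
        pub["delta_qaly"], abs=0.02
    )
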
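"""Incremental comparison, detected-cohort scaling and calibration tests."""

from dataclasses import replace

import pytest
from hypothesis import given, strategies as st

from crcua.conversions import BGN_PER_EUR
from crcua.cua import (
    ArmResult,
    CalibrationTargets,
    calibrate_variant,
    compare_arms,
    default_variant_grid,
    estimate_detected,
    evaluate_arms,
    scale_results,
)
from crcua.markov import WITH_SCREENING, WITHOUT_SCREENING, StructuralVariant


def _res(cost, qaly, label="a"):
    return ArmResult(label, cost, qaly)


class TestCompareArms:
    def test_published_base_case_is_dominant(self):
        inc = compare_arms(_res(1137.24, 8.46), _res(1204.31, 6.88))
        assert inc.classification == "dominant"
        assert inc.delta_cost == pytest.approx(-67.07, abs=1e-9)
        assert inc.delta_qaly == pytest.approx(1.58, abs=1e-9)
        assert inc.icur is None

    def test_identical_arms_are_equivalent(self):
        inc = compare_arms(_res(100.0, 5.0), _res(100.0, 5.0))
        assert inc.classification == "equivalent"
        assert (inc.delta_cost, inc.delta_qaly) == (0.0, 0.0)

    def test_same_sign_deltas_define_icur(self):
        inc = compare_arms(_res(1100.0, 9.0), _res(1000.0, 8.0))
        assert inc.classification == "icur_defined"
        assert inc.icur == pytest.approx(100.0)

    def test_costlier_and_less_effective_is_dominated(self):
        assert compare_arms(_res(1100.0, 7.0), _res(1000.0, 8.0)).classification == "dominated"

    def test_zero_qaly_delta_classified_by_cost_alone(self):
        inc = compare_arms(_res(900.0, 8.0), _res(1000.0, 8.0))
        assert inc.classification == "dominant"
        assert inc.icur is None

    @given(
        ca=st.floats(0, 1e5), qa=st.floats(0, 50),
        cb=st.floats(0, 1e5), qb=st.floats(0, 50),
    )
    def test_antisymmetry(self, ca, qa, cb, qb):
        fwd = compare_arms(_res(ca, qa), _res(cb, qb))
        rev = compare_arms(_res(cb, qb), _res(ca, qa))
        assert fwd.delta_cost == -rev.delta_cost
        assert fwd.delta_qaly == -rev.delta_qaly

    @given(
        ca=st.floats(0, 1e5), qa=st.floats(0, 50),
        cb=st.floats(0, 1e5), qb=st.floats(0, 50),
    )
    def test_dominance_invariant_under_currency_conversion(self, ca, qa, cb, qb):
        eur = compare_arms(_res(ca, qa), _res(cb, qb))
        bgn = compare_arms(_res(ca * BGN_PER_EUR, qa), _res(cb * BGN_PER_EUR, qb))
        assert eur.classification == bgn.classification


class TestDetectedCohort:
    def test_slovenian_rate_applied_to_bulgarian_positives(self):
        cohort = estimate_detected(13263, 862, 15310)
        assert round(cohort.detection_rate, 4) == 0.0563
        assert cohort.n_detected == 747

    @pytest.mark.parametrize(
        "positives, expected", [(15310, 862), (0, 0)]
    )
    def test_degenerate_applications(self, positives, expected):
        assert estimate_detected(positives, 862, 15310).n_detected == expected

    def test_zero_reference_positive_rejected(self):
        with pytest.raises(ValueError):
            estimate_detected(100, 10, 0)

    def test_detected_never_exceeds_positives(self):
        cohort = estimate_detected(13263, 862, 15310)
        assert cohort.n_detected <= cohort.fit_positive_count


class TestScaleResults:
    def test_model_deltas_scale_to_published_cohort_totals(self, base_config, published):
        res_with, res_without = evaluate_arms(base_config)
        inc = compare_arms(res_with, res_without)
        scaled = scale_results(inc, estimate_detected(13263))
        pub = published["detected_cohort_totals"]
        assert scaled.delta_cost == pytest.approx(pub["delta_cost"], rel=0.02)
        assert scaled.delta_qaly == pytest.approx(pub["delta_qaly"], rel=0.02)
        assert scaled.classification == "dominant"

    @pytest.mark.parametrize("n, factor", [(0, 0.0), (1, 1.0)])
    def test_degenerate_scales(self, n, factor):
        inc = compare_arms(_res(900.0, 9.0), _res(1000.0, 8.0))
        scaled = scale_results(inc, n)
        assert scaled.delta_cost == inc.delta_cost * factor
        assert scaled.delta_qaly == inc.delta_qaly * factor

    @given(n=st.integers(0, 1000), m=st.integers(0, 1000))
    def test_scaling_is_multiplicative(self, n, m):
        inc = compare_arms(_res(900.0, 9.0), _res(1000.0, 8.0))
        twice = scale_results(scale_results(inc, n), m)
        once = scale_results(inc, n * m)
        assert twice.delta_cost == pytest.approx(once.delta_cost, rel=1e-12, abs=1e-12)
        assert twice.delta_qaly == pytest.approx(once.delta_qaly, rel=1e-12, abs=1e-12)


class TestCalibration:
    def test_recovers_generating_variant_from_synthetic_targets(self, base_config):
        """Targets generated under a known structural variant rank that
        variant first with (numerically) zero error."""
        generating = StructuralVariant(
            diagnosis_timing="at_entry",
            half_cycle_correction=True,
            late_cost_recurrence="once_on_entry",
            colonoscopy_charge="early_only",
            transition_cost_timing="arrival",
        )
        cfg = base_config.with_variant(generating)
        res_with, res_without = evaluate_arms(cfg)
        targets = CalibrationTargets(
            res_with.total_cost, res_with.total_qaly,
            res_without.total_cost, res_without.total_qaly,
        )
        ranking = calibrate_variant(targets, base_config)
        assert ranking[0].variant == generating
        assert ranking[0].error == pytest.approx(0.0, abs=1e-12)

    def test_single_variant_grid_returns_it(self, base_config, calibration_targets):
        only = StructuralVariant()
        ranking = calibrate_variant(calibration_targets, base_config, grid=[only])
        assert len(ranking) == 1 and ranking[0].variant == only

    def test_empty_grid_rejected(self, base_config, calibration_targets):
        with pytest.raises(ValueError):
            calibrate_variant(calibration_targets, base_config, grid=[])

    def test_default_grid_has_64_distinct_variants(self):
        grid = default_variant_grid()
        assert len(grid) == len(set(grid)) == 64

    def test_grid_search_selects_shipped_default_for_published_targets(
        self, base_config, calibration_targets
    ):
        ranking = calibrate_variant(calibration_targets, base_config)
        assert ranking[0].variant == StructuralVariant()
        assert ranking[0].error < ranking[1].error  # unambiguous winner
        inc = compare_arms(ranking[0].with_screening, ranking[0].without_screening)
        assert abs(inc.delta_qaly - 1.58) < 0.02
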
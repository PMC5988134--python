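"""Payoffs, QALY arithmetic and calibration of the outcome constants."""

import pytest

from spectriage import (CalibrationError, CohortSpec, ParameterError,
                        calibrate_avoided_cost, calibrate_gain,
                        calibrate_monitoring_time, default_calibration,
                        qaly_from_survival, terminal_payoff)
from spectriage.scenarios import (DISEASED_NO_TEST, TN_SKIPPED, TP_ROUTE)


class TestQALYFromSurvival:
    def test_one_year_at_base_utility(self):
        assert qaly_from_survival(365.25, 0.89, 730) == pytest.approx(0.89)

    def test_horizon_truncation(self):
        assert qaly_from_survival(1000, 1.0, 730) == pytest.approx(730 / 365.25)

    def test_zero_survival(self):
        assert qaly_from_survival(0, 0.89, 730) == 0.0

    def test_negative_input_rejected(self):
        with pytest.raises(ParameterError):
            qaly_from_survival(-1, 0.89, 730)

    def test_discounting_reduces_second_year_only(self):
        undiscounted = qaly_from_survival(730, 1.0, 730)
        discounted = qaly_from_survival(730, 1.0, 730, discount_rate=0.035)
        # 730 days = 1 full year + 364.75 days; only the second year is
        # discounted (annual compounding)
        assert discounted == pytest.approx(1 + (364.75 / 365.25) / 1.035)
        assert discounted < undiscounted
        # first year unaffected
        assert qaly_from_survival(365.25, 1.0, 730, discount_rate=0.035) \
            == pytest.approx(1.0)


class TestCalibrateGain:
    def test_secondary_care_target(self):
        g = calibrate_gain(52.86, CohortSpec(10_000, 0.03), 0.928)
        assert g == pytest.approx(52.86 / 278.4)
        assert g == pytest.approx(0.18987, abs=5e-6)

    def test_cross_scenario_consistency(self):
        """g calibrated on either published ΔQALY agrees to 3 s.f."""
        g2 = calibrate_gain(52.86, CohortSpec(10_000, 0.03), 0.928)
        g1 = calibrate_gain(8.81, CohortSpec(10_000, 0.005), 0.928)
        assert g1 == pytest.approx(g2, rel=5e-4)

    def test_zero_target_gives_zero_gain(self):
        assert calibrate_gain(0.0, CohortSpec(10_000, 0.03), 0.928) == 0.0

    def test_zero_true_positive_mass_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_gain(10.0, CohortSpec(10_000, 0.03), 0.0)


class TestCalibrateCosts:
    def test_avoided_cost_primary_uk(self, uk_primary):
        c = calibrate_avoided_cost(-422_116, uk_primary)
        assert c == pytest.approx(203.5, abs=0.01)

    def test_avoided_cost_zero_savings_limit(self, uk_primary):
        """Target equal to test cost plus monitoring term → c_avoid = 0."""
        tp = 10_000 * 0.005 * 0.928
        target = (10_000 * 50
                  + tp * uk_primary.outcomes.extra_monitoring_years_per_tp
                  * uk_primary.costs.monitoring_per_year)
        assert calibrate_avoided_cost(target, uk_primary) == \
            pytest.approx(0.0, abs=1e-9)

    def test_avoided_cost_unidentifiable_in_secondary(self, uk_secondary):
        with pytest.raises(CalibrationError, match="not identifiable"):
            calibrate_avoided_cost(527_646, uk_secondary)

    def test_monitoring_time_secondary_uk(self, uk_secondary):
        delta = calibrate_monitoring_time(527_646, uk_secondary)
        assert delta == pytest.approx(27_646 / (278.4 * 464))

    def test_monitoring_time_unidentifiable_in_primary(self, uk_primary):
        with pytest.raises(CalibrationError, match="not identifiable"):
            calibrate_monitoring_time(-422_116, uk_primary)

    def test_default_calibration_roundtrip(self, uk_primary, uk_secondary):
        """The shipped constants are fixed points of the calibration ops."""
        calib = default_calibration("UK")
        assert calibrate_gain(52.86, uk_secondary.cohort, 0.928) == \
            pytest.approx(calib.gain_per_tp)
        assert calibrate_monitoring_time(527_646, uk_secondary) == \
            pytest.approx(calib.extra_monitoring_years_per_tp)
        assert calibrate_avoided_cost(-422_116, uk_primary) == \
            pytest.approx(calib.avoided_cost_per_skipped_workup)


class TestTerminalPayoff:
    def test_fast_tracked_true_positive_components(self, uk_primary):
        p = terminal_payoff(TP_ROUTE, uk_primary, with_test=True)
        assert p.test == 50
        assert p.workup == pytest.approx(
            uk_primary.outcomes.avoided_cost_per_skipped_workup)
        assert p.workup > 164  # bundle covers the MRI scan and visits
        # monitoring over (1 year + δ) at £116/quarter
        expected_years = 1.0 + uk_primary.outcomes.extra_monitoring_years_per_tp
        assert p.monitoring == pytest.approx(464 * expected_years)
        assert p.qaly == pytest.approx(
            0.89 + uk_primary.outcomes.qaly_gain_per_true_positive)

    def test_skipped_route_costs_test_only(self, uk_primary):
        p = terminal_payoff(TN_SKIPPED, uk_primary, with_test=True)
        assert p.cost == pytest.approx(50)
        assert p.workup == 0 and p.monitoring == 0

    def test_monitoring_rate_one_year(self, uk_primary):
        p = terminal_payoff(DISEASED_NO_TEST, uk_primary, with_test=False)
        assert p.monitoring == pytest.approx(464)  # £116 per quarter × 4

    def test_itemised_costing_uses_unit_costs(self, uk_primary):
        p = uk_primary.replace(**{"pathway.workup_costing": "itemised"})
        payoff = terminal_payoff(DISEASED_NO_TEST, p, with_test=False)
        assert payoff.workup == pytest.approx(164 + 35)  # MRI + neurology

    def test_non_diseased_qaly_identical_across_arms(self, uk_primary):
        a = terminal_payoff(TN_SKIPPED, uk_primary, True).qaly
        from spectriage.scenarios import HEALTHY_NO_TEST
        b = terminal_payoff(HEALTHY_NO_TEST, uk_primary, False).qaly
        assert a == b == pytest.approx(0.89 * 730 / 365.25)

    def test_qaly_bounded_by_utility_times_horizon(self, uk_primary,
                                                   random_params_factory):
        import numpy as np
        from spectriage.scenarios import (FN_IMAGED, FP_ROUTE, TN_IMAGED)
        rng = np.random.default_rng(2)
        routes = [TP_ROUTE, FN_IMAGED, FP_ROUTE, TN_IMAGED, TN_SKIPPED]
        for _ in range(10):
            params = random_params_factory(rng)
            cap = params.outcomes.utility * params.outcomes.horizon_years
            for route in routes:
                payoff = terminal_payoff(route, params, True)
                assert payoff.qaly <= cap + params.outcomes.qaly_gain_per_true_positive + 1e-12
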
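"""OWSA curves, threshold search, and named scenario analyses."""

import numpy as np
import pytest

from spectriage import (ParameterError, apply_scenario, evaluate,
                        find_threshold, owsa, scenario_analysis,
                        set_parameter)


class TestOWSA:
    def test_specificity_leaves_delta_qaly_constant(self, uk_primary):
        curve = owsa(uk_primary, "specificity", np.linspace(0.7, 0.99, 8))
        dqs = {round(r.delta_qaly, 9) for r in curve.results}
        assert len(dqs) == 1
        # ... so ICER movement is purely cost-driven
        assert len({round(r.delta_cost) for r in curve.results}) == 8

    def test_test_cost_step_shifts_cost_by_n_delta(self, uk_primary):
        curve = owsa(uk_primary, "test_cost", [50, 100])
        assert curve.results[1].delta_cost - curve.results[0].delta_cost \
            == pytest.approx(10_000 * 50)
        assert curve.results[1].delta_qaly == \
            pytest.approx(curve.results[0].delta_qaly)

    def test_sensitivity_moves_both_increments(self, uk_secondary):
        curve = owsa(uk_secondary, "sensitivity", [0.8, 0.9, 0.99])
        assert len({round(r.delta_qaly, 6) for r in curve.results}) == 3
        assert len({round(r.delta_cost, 2) for r in curve.results}) == 3

    def test_grid_must_increase(self, uk_primary):
        with pytest.raises(ParameterError):
            owsa(uk_primary, "specificity", [0.9, 0.8])

    def test_unknown_parameter(self, uk_primary):
        with pytest.raises(ParameterError, match="unknown"):
            owsa(uk_primary, "telepathy", [0.1, 0.2])

    def test_frame_shape(self, uk_primary):
        frame = owsa(uk_primary, "prevalence",
                     np.linspace(0.002, 0.02, 5)).to_frame()
        assert list(frame.columns) == ["prevalence", "delta_cost",
                                       "delta_qaly", "icer", "dominance"]
        assert len(frame) == 5


class TestMonotonicity:
    def test_icer_nonincreasing_in_specificity_primary(self, uk_primary):
        """More true negatives → more avoided work-ups → lower ΔCost with
        ΔQALY fixed, so the ICER falls as specificity improves."""
        curve = owsa(uk_primary, "specificity", np.linspace(0.6, 0.99, 10))
        icers = [r.icer for r in curve.results]
        assert all(b <= a + 1e-9 for a, b in zip(icers, icers[1:]))

    def test_icer_increasing_in_test_cost_with_exact_slope(self, uk_secondary):
        grid = [25.0, 50.0, 100.0, 200.0]
        curve = owsa(uk_secondary, "test_cost", grid)
        icers = [r.icer for r in curve.results]
        assert all(b > a for a, b in zip(icers, icers[1:]))
        dq = curve.results[0].delta_qaly
        slope = (icers[-1] - icers[0]) / (grid[-1] - grid[0])
        assert slope == pytest.approx(10_000 / dq, rel=1e-9)


class TestFindThreshold:
    def test_specificity_threshold_at_upper_test_cost(self, uk_primary):
        """At the £100 price, the specificity at which the ICER reaches
        £30,000/QALY lies in (0.7, 0.95), and re-evaluating at the
        returned value recovers the limit."""
        base = set_parameter(uk_primary, "test_cost", 100.0)
        x = find_threshold(base, "specificity", 30_000)
        assert 0.7 < x < 0.95
        res = evaluate(set_parameter(base, "specificity", x))
        assert res.icer == pytest.approx(30_000, abs=50)

    def test_dominant_throughout_returns_none(self, uk_primary):
        # at £50 the primary-care ICER stays far below £200k over the range
        assert find_threshold(uk_primary, "specificity", 200_000,
                              bounds=(0.7, 0.99)) is None

    def test_test_cost_threshold_fixed_point(self, uk_secondary):
        x = find_threshold(uk_secondary, "test_cost", 20_000,
                           bounds=(10.0, 500.0), tol=1e-6)
        res = evaluate(set_parameter(uk_secondary, "test_cost", x))
        assert res.icer == pytest.approx(20_000, abs=1)


class TestScenarioAnalyses:
    def test_prevalence_1pct_doubles_delta_qaly(self, uk_primary):
        base = evaluate(uk_primary)
        res = scenario_analysis(uk_primary, "prevalence_1pct")
        assert res.delta_qaly == pytest.approx(2 * base.delta_qaly)
        # at the £100 price (positive ICERs) the higher prevalence
        # substantially reduces the ICER
        upper = set_parameter(uk_primary, "test_cost", 100.0)
        assert (scenario_analysis(upper, "prevalence_1pct").icer
                < evaluate(upper).icer)

    def test_consultation_addon_is_cost_only(self, uk_primary):
        base = evaluate(uk_primary)
        res = scenario_analysis(uk_primary, "consultation_addon")
        assert res.delta_qaly == pytest.approx(base.delta_qaly)
        assert res.delta_cost > base.delta_cost

    def test_higher_imaging_after_negative_raises_cost(self, uk_primary):
        base = evaluate(uk_primary)
        res = scenario_analysis(uk_primary, "higher_imaging_after_negative")
        assert res.delta_cost > base.delta_cost
        assert res.delta_qaly == pytest.approx(base.delta_qaly)

    def test_mean_survival_leaves_increments_unchanged(self, uk_primary):
        """Baseline survival appears identically in both arms, so switching
        the survival summary moves absolute outcomes but not increments."""
        base = evaluate(uk_primary)
        res = scenario_analysis(uk_primary, "mean_survival")
        assert res.delta_cost == pytest.approx(base.delta_cost, abs=1e-6)
        assert res.delta_qaly == pytest.approx(base.delta_qaly, abs=1e-9)

    def test_toggles_change_only_named_parameters(self, uk_primary):
        diffs = {
            "consultation_addon": {("pathway", "consultation_addon")},
            "higher_imaging_after_negative": {("pathway",
                                               "p_image_after_negative")},
            "mean_survival": {("pathway", "survival_summary"),
                              ("outcomes", "baseline_survival_days")},
            "prevalence_1pct": {("cohort", "prevalence")},
        }
        base_dict = uk_primary.to_dict()
        for which, expected in diffs.items():
            new = apply_scenario(uk_primary, which).to_dict()
            changed = {(group, key)
                       for group, sub in base_dict.items()
                       if isinstance(sub, dict)
                       for key in sub
                       if new[group][key] != sub[key]}
            assert changed == expected

    def test_unknown_scenario(self, uk_primary):
        with pytest.raises(ParameterError):
            scenario_analysis(uk_primary, "free_scanners")
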
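"""One-way sensitivity analysis, threshold search, and named scenario analyses.

OWSA re-runs the full pipeline over a grid of one parameter with everything
else fixed. Results are returned as (ΔCost, ΔQALY, ICER) per grid point —
suitable for a cost-effectiveness plane. Threshold search bisects the
parameter value at which the ICER crosses a willingness-to-pay limit,
after checking numerically that the ICER is monotone over the range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cea import IncrementalResult, evaluate
from .errors import ParameterError
from .parameters import ALTERNATIVE_PRIMARY_PREVALENCE, ParameterSet

#: parameters OWSA can vary, with the dotted field they map to and the
#: default search range for threshold finding
OWSA_PARAMETERS = {
    "sensitivity": ("test.sensitivity", (0.5, 0.999)),
    "specificity": ("test.specificity", (0.5, 0.999)),
    "test_cost": ("costs.test_cost", (1.0, 1000.0)),
    "prevalence": ("cohort.prevalence", (1e-4, 0.2)),
    "utility": ("outcomes.utility", (0.05, 1.0)),
    "p_image_after_negative": ("pathway.p_image_after_negative", (0.0, 1.0)),
}

#: mean survival summary for high-grade glioma used by the mean-survival
#: scenario (≈ 15 months vs the 12-month median); affects only monitoring
#: terms, which cancel between arms, so results are robust to this choice
MEAN_SURVIVAL_DAYS = 456.0


def set_parameter(base: ParameterSet, parameter: str,
                  value: float) -> ParameterSet:
    """New parameter set with one OWSA parameter replaced (revalidated)."""
    if parameter not in OWSA_PARAMETERS:
        raise ParameterError(parameter,
                             f"unknown OWSA parameter; choose from "
                             f"{sorted(OWSA_PARAMETERS)}")
    path, _ = OWSA_PARAMETERS[parameter]
    return base.replace(**{path: value})


@dataclass(frozen=True)
class OWSACurve:
    """ICER (and increments) as a function of one varied parameter."""

    parameter: str
    grid: tuple[float, ...]
    results: tuple[IncrementalResult, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            self.parameter: self.grid,
            "delta_cost": [r.delta_cost for r in self.results],
            "delta_qaly": [r.delta_qaly for r in self.results],
            "icer": [r.icer for r in self.results],
            "dominance": [r.dominance for r in self.results],
        })


def owsa(base: ParameterSet, parameter: str, grid) -> OWSACurve:
    """Re-run the full pipeline at each grid value of one parameter."""
    grid = tuple(float(g) for g in grid)
    if any(b >= a for a, b in zip(grid[1:], grid)):
        raise ParameterError(parameter, "grid must be strictly increasing")
    results = tuple(evaluate(set_parameter(base, parameter, g)) for g in grid)
    return OWSACurve(parameter=parameter, grid=grid, results=results)


def find_threshold(base: ParameterSet, parameter: str, icer_limit: float,
                   bounds: tuple[float, float] | None = None,
                   tol: float = 1e-4, check_points: int = 9) -> float | None:
    """Parameter value where the ICER crosses ``icer_limit``, by bisection.

    Returns ``None`` if the ICER never crosses the limit over the search
    range (e.g. a configuration that dominates throughout). Raises if the
    ICER is not numerically monotone over the range, since a bisection
    root would then be ambiguous.
    """
    if parameter not in OWSA_PARAMETERS:
        raise ParameterError(parameter, "unknown OWSA parameter")
    if bounds is None:
        bounds = OWSA_PARAMETERS[parameter][1]
    lo, hi = bounds

    def icer_at(x: float) -> float:
        res = evaluate(set_parameter(base, parameter, x))
        if res.icer is None:
            raise ParameterError(parameter,
                                 f"ICER undefined (ΔQALY = 0) at {x}")
        return res.icer

    probe = np.linspace(lo, hi, check_points)
    values = np.array([icer_at(x) for x in probe])
    diffs = np.diff(values)
    scale = max(1.0, np.abs(values).max()) * 1e-9
    if not ((diffs >= -scale).all() or (diffs <= scale).all()):
        raise ParameterError(
            parameter, "ICER is not monotone over the search range; "
            "no unambiguous threshold exists")
    f_lo, f_hi = values[0] - icer_limit, values[-1] - icer_limit
    if f_lo == 0.0:
        return float(lo)
    if f_hi == 0.0:
        return float(hi)
    if np.sign(f_lo) == np.sign(f_hi):
        return None
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        f_mid = icer_at(mid) - icer_limit
        if f_mid == 0.0:
            return float(mid)
        if np.sign(f_mid) == np.sign(f_lo):
            lo, f_lo = mid, f_mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


#: named scenario analyses (assumption toggles). Magnitudes for the
#: consultation add-on and the higher post-negative imaging proportion are
#: not published; the defaults below are documented package choices.
SCENARIO_ANALYSES = ("consultation_addon", "higher_imaging_after_negative",
                     "mean_survival", "prevalence_1pct")

HIGHER_P_IMAGE_AFTER_NEGATIVE = 0.75


def apply_scenario(base: ParameterSet, which: str) -> ParameterSet:
    """Copy of ``base`` with one named assumption toggled."""
    if which == "consultation_addon":
        # discussing a positive result costs one visit: GP in primary care,
        # neurology outpatient in secondary care
        visit = (base.costs.gp_visit if base.scenario == "primary"
                 else base.costs.neurology_outpatient)
        return base.replace(**{"pathway.consultation_addon": visit})
    if which == "higher_imaging_after_negative":
        return base.replace(**{"pathway.p_image_after_negative":
                               HIGHER_P_IMAGE_AFTER_NEGATIVE})
    if which == "mean_survival":
        return base.replace(**{"pathway.survival_summary": "mean",
                               "outcomes.baseline_survival_days":
                               MEAN_SURVIVAL_DAYS})
    if which == "prevalence_1pct":
        return base.replace(**{"cohort.prevalence":
                               ALTERNATIVE_PRIMARY_PREVALENCE})
    raise ParameterError("scenario_analysis",
                         f"unknown scenario {which!r}; choose from "
                         f"{SCENARIO_ANALYSES}")


def scenario_analysis(base: ParameterSet, which: str) -> IncrementalResult:
    """Incremental result under one named assumption toggle."""
    return evaluate(apply_scenario(base, which))
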
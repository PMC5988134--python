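"""Typed model inputs, country cost tables, defaults and config loading.

Every numeric input of one model run is bundled into a :class:`ParameterSet`.
All containers validate on construction (and therefore on
``dataclasses.replace``), so an invalid parameter set cannot reach the model;
errors name the offending field with a dotted path (``cohort.prevalence``).

Base-case values
----------------
* Test performance: sensitivity 92.8% (SD 1.1%), specificity 91.5% (SD 1.9%),
  estimated from repeated random-forest classification of serum FTIR spectra
  in a case-control series.
* Prevalence: 0.5% among patients eligible for direct-access imaging in
  primary care (1% packaged as an alternative), 3% among patients referred
  for imaging from secondary care.
* Unit costs: UK NHS reference costs / PSSRU (2015 prices) and USA Medicare
  schedules (2016 prices); test price bounds £50-£100 and $100-$200.
* Utility weight 0.89 for stable disease, 2-year horizon, no discounting.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .errors import ParameterError

SCENARIOS = ("primary", "secondary")
COUNTRIES = ("UK", "USA")

#: days per year used throughout when converting survival time to life-years
DAYS_PER_YEAR = 365.25

#: Unit costs per country (currency units). ``monitoring_per_quarter`` is the
#: stable-disease monitoring cost per 3 months.
UK_UNIT_COSTS = {
    "currency": "GBP",
    "ct_scan": 85.0,
    "mri_scan": 164.0,
    "neurology_outpatient": 35.0,
    "gp_visit": 47.25,
    "monitoring_per_quarter": 116.0,
}
USA_UNIT_COSTS = {
    "currency": "USD",
    "ct_scan": 163.0,
    "mri_scan": 380.0,
    "neurology_outpatient": 76.0,
    "gp_visit": 76.0,
    "monitoring_per_quarter": 154.0,
}

#: default test price (lower bound of the assumed price range) per country
DEFAULT_TEST_COST = {"UK": 50.0, "USA": 100.0}

#: base-case disease prevalence per care setting
DEFAULT_PREVALENCE = {"primary": 0.005, "secondary": 0.03}

#: packaged alternative primary-care prevalence (named config, not a scenario)
ALTERNATIVE_PRIMARY_PREVALENCE = 0.01

#: probability a test-negative patient still proceeds to imaging
DEFAULT_P_IMAGE_AFTER_NEGATIVE = {"primary": 0.5, "secondary": 1.0}


def _check(cond: bool, field_path: str, message: str) -> None:
    if not cond:
        raise ParameterError(field_path, message)


@dataclass(frozen=True)
class TestPerformance:
    """Diagnostic accuracy of the triage test with sampling uncertainty.

    The standard deviations must be small enough that a beta distribution
    with matching first two moments exists (sd² < m(1−m)), since the
    probabilistic sensitivity analysis samples moment-matched betas.
    """

    __test__ = False  # not a test class despite the name

    sensitivity: float = 0.928
    specificity: float = 0.915
    sd_sensitivity: float = 0.011
    sd_specificity: float = 0.019

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity"):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, f"test.{name}", f"must be in [0, 1], got {v}")
        for name, m in (("sd_sensitivity", self.sensitivity),
                        ("sd_specificity", self.specificity)):
            sd = getattr(self, name)
            _check(sd >= 0.0, f"test.{name}", f"must be non-negative, got {sd}")
            if sd > 0.0 and 0.0 < m < 1.0:
                _check(sd * sd < m * (1.0 - m), f"test.{name}",
                       f"sd²={sd*sd:g} not < m(1−m)={m*(1-m):g}; "
                       "no beta distribution matches these moments")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort size and disease prevalence."""

    size: int = 10_000
    prevalence: float = 0.005

    def __post_init__(self) -> None:
        _check(self.size > 0, "cohort.size", f"must be positive, got {self.size}")
        _check(0.0 < self.prevalence < 1.0, "cohort.prevalence",
               f"must be in (0, 1), got {self.prevalence}")


@dataclass(frozen=True)
class CostTable:
    """Unit costs in one currency.

    ``fast_track_premium`` is the extra cost of a fast-tracked imaging
    episode over a routine one; the source prices fast-track imaging
    identically to routine imaging, so it defaults to 0 and exists for
    exploring the cost of false-positive-driven fast-track volume.
    """

    currency: str = "GBP"
    ct_scan: float = 85.0
    mri_scan: float = 164.0
    neurology_outpatient: float = 35.0
    gp_visit: float = 47.25
    monitoring_per_quarter: float = 116.0
    test_cost: float = 50.0
    fast_track_premium: float = 0.0

    def __post_init__(self) -> None:
        _check(self.currency in ("GBP", "USD"), "costs.currency",
               f"must be GBP or USD, got {self.currency!r}")
        for f in fields(self):
            if f.name == "currency":
                continue
            v = getattr(self, f.name)
            _check(v >= 0.0, f"costs.{f.name}", f"must be non-negative, got {v}")

    @property
    def monitoring_per_year(self) -> float:
        """Annualised stable-disease monitoring cost (4 quarters)."""
        return 4.0 * self.monitoring_per_quarter

    @classmethod
    def for_country(cls, country: str, test_cost: float | None = None,
                    **overrides: float) -> "CostTable":
        _check(country in COUNTRIES, "country",
               f"must be one of {COUNTRIES}, got {country!r}")
        base = UK_UNIT_COSTS if country == "UK" else USA_UNIT_COSTS
        if test_cost is None:
            test_cost = DEFAULT_TEST_COST[country]
        return cls(test_cost=float(test_cost), **{**base, **overrides})


@dataclass(frozen=True)
class PathwayParams:
    """Routing rules and delay classes of the diagnostic pathway.

    Delay classes condition time-to-diagnosis: D1 = fast-tracked (1 week),
    D2 = standard (4 weeks), D3 = late/emergency presentation (8 weeks,
    reserved; not routed by default).

    ``workup_costing`` selects how the imaging work-up (scan plus associated
    clinic/GP visits) is priced: ``"calibrated"`` uses the avoided-work-up
    bundle cost recovered from the published increments; ``"itemised"``
    builds it from unit costs and ``workup_visits``.
    """

    p_image_after_negative: float = 0.5
    consultation_addon: float = 0.0
    survival_summary: str = "median"  # "median" | "mean"
    delay_fast: float = 7.0
    delay_standard: float = 28.0
    delay_late: float = 56.0
    workup_costing: str = "calibrated"  # "calibrated" | "itemised"
    #: visit counts per imaging work-up, used only in itemised costing
    workup_visits: tuple[tuple[str, float], ...] = (("neurology_outpatient", 1.0),)
    #: CT fraction of the definitive imaging mix (remainder MRI)
    ct_fraction: float = 0.0

    def __post_init__(self) -> None:
        _check(0.0 <= self.p_image_after_negative <= 1.0,
               "pathway.p_image_after_negative",
               f"must be in [0, 1], got {self.p_image_after_negative}")
        _check(self.consultation_addon >= 0.0, "pathway.consultation_addon",
               "must be non-negative")
        _check(self.survival_summary in ("median", "mean"),
               "pathway.survival_summary", "must be 'median' or 'mean'")
        _check(0.0 < self.delay_fast < self.delay_standard < self.delay_late,
               "pathway.delay_fast",
               "delay classes must satisfy 0 < D1 < D2 < D3")
        _check(self.workup_costing in ("calibrated", "itemised"),
               "pathway.workup_costing", "must be 'calibrated' or 'itemised'")
        _check(0.0 <= self.ct_fraction <= 1.0, "pathway.ct_fraction",
               "must be in [0, 1]")


@dataclass(frozen=True)
class OutcomeParams:
    """Utility, horizon and the calibrated outcome constants.

    The natural-history survival-by-delay values behind the published model
    live in unavailable supplementary material; under the 2-year horizon
    they collapse to three identifiable constants, recovered by calibration
    against the published increments (see :mod:`spectriage.outcomes`):

    * ``qaly_gain_per_true_positive`` (g) — QALYs gained by each tumour
      patient whose diagnosis is fast-tracked by a positive test;
    * ``extra_monitoring_years_per_tp`` (δ) — additional monitored survival
      time per true positive, carrying monitoring cost;
    * ``avoided_cost_per_skipped_workup`` (c_avoid) — cost of the imaging
      work-up bundle avoided when a test-negative patient does not proceed
      to imaging.
    """

    utility: float = 0.89
    horizon_days: float = 730.0
    qaly_gain_per_true_positive: float = 0.0
    avoided_cost_per_skipped_workup: float = 0.0
    extra_monitoring_years_per_tp: float = 0.0
    discount_rate: float = 0.0
    #: diseased patients' baseline survival used for monitoring-cost terms
    #: (median ≈ 1 year for high-grade glioma; the mean-survival scenario
    #: uses a longer summary, see sensitivity.scenario_analysis)
    baseline_survival_days: float = 365.25

    def __post_init__(self) -> None:
        _check(0.0 <= self.utility <= 1.0, "outcomes.utility",
               f"must be in [0, 1], got {self.utility}")
        _check(self.horizon_days > 0.0, "outcomes.horizon_days", "must be positive")
        _check(self.qaly_gain_per_true_positive >= 0.0,
               "outcomes.qaly_gain_per_true_positive", "must be non-negative")
        _check(self.avoided_cost_per_skipped_workup >= 0.0,
               "outcomes.avoided_cost_per_skipped_workup", "must be non-negative")
        _check(self.extra_monitoring_years_per_tp >= 0.0,
               "outcomes.extra_monitoring_years_per_tp", "must be non-negative")
        _check(self.discount_rate >= 0.0, "outcomes.discount_rate",
               "must be non-negative")
        _check(0.0 < self.baseline_survival_days,
               "outcomes.baseline_survival_days", "must be positive")

    @property
    def horizon_years(self) -> float:
        return self.horizon_days / DAYS_PER_YEAR


@dataclass(frozen=True)
class ParameterSet:
    """Every numeric input of one model run, validated as a whole."""

    test: TestPerformance = field(default_factory=TestPerformance)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    costs: CostTable = field(default_factory=CostTable)
    pathway: PathwayParams = field(default_factory=PathwayParams)
    outcomes: OutcomeParams = field(default_factory=OutcomeParams)
    scenario: str = "primary"
    country: str = "UK"

    def __post_init__(self) -> None:
        _check(self.scenario in SCENARIOS, "scenario",
               f"must be one of {SCENARIOS}, got {self.scenario!r}")
        _check(self.country in COUNTRIES, "country",
               f"must be one of {COUNTRIES}, got {self.country!r}")

    def validate(self) -> None:
        """Re-run every invariant check; raises ParameterError on failure."""
        for f in fields(self):
            v = getattr(self, f.name)
            if dataclasses.is_dataclass(v):
                dataclasses.replace(v)
        dataclasses.replace(self)

    def replace(self, **kwargs: Any) -> "ParameterSet":
        """``dataclasses.replace`` accepting dotted nested paths.

        ``params.replace(**{"test.specificity": 0.8})`` returns a new,
        revalidated parameter set differing only in that field.
        """
        flat = {}
        for key, value in kwargs.items():
            if "." in key:
                group, name = key.split(".", 1)
                current = flat.get(group, getattr(self, group))
                flat[group] = dataclasses.replace(current, **{name: value})
            else:
                flat[key] = value
        return dataclasses.replace(self, **flat)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ParameterSet":
        return _build(cls, data, path="")

    def save_config(self, path: str | Path) -> None:
        """Write the parameter set as a YAML config file."""
        d = self.to_dict()
        # tuples -> lists for clean YAML
        d["pathway"]["workup_visits"] = [list(v) for v in
                                         d["pathway"]["workup_visits"]]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


_GROUP_TYPES = {
    "test": TestPerformance,
    "cohort": CohortSpec,
    "costs": CostTable,
    "pathway": PathwayParams,
    "outcomes": OutcomeParams,
}


def _build(cls, data: dict, path: str):
    """Construct a (possibly nested) dataclass, rejecting unknown keys."""
    known = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, value in data.items():
        where = f"{path}{key}"
        if key not in known:
            raise ParameterError(where, "unknown configuration key")
        if key in _GROUP_TYPES and isinstance(value, dict):
            kwargs[key] = _build(_GROUP_TYPES[key], value, path=f"{where}.")
        elif key == "workup_visits":
            kwargs[key] = tuple((str(n), float(c)) for n, c in value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def default_parameters(scenario: str = "primary", country: str = "UK",
                       test_cost: float | None = None) -> ParameterSet:
    """Fully populated base-case parameter set for one published cell.

    Prevalence is 0.5% for the primary-care setting and 3% for the
    secondary-care setting; all test-negative patients proceed to imaging
    in secondary care versus 50% in primary care; unit costs come from the
    requested country's cost table; the calibrated outcome constants are
    recovered from the published increments at import of the outcomes
    module (closed-form, deterministic).
    """
    _check(scenario in SCENARIOS, "scenario",
           f"must be one of {SCENARIOS}, got {scenario!r}")
    _check(country in COUNTRIES, "country",
           f"must be one of {COUNTRIES}, got {country!r}")
    if test_cost is not None:
        _check(test_cost > 0, "costs.test_cost",
               f"must be positive, got {test_cost}")
    from .outcomes import default_calibration  # deferred: avoids import cycle

    calib = default_calibration(country)
    return ParameterSet(
        test=TestPerformance(),
        cohort=CohortSpec(size=10_000, prevalence=DEFAULT_PREVALENCE[scenario]),
        costs=CostTable.for_country(country, test_cost),
        pathway=PathwayParams(
            p_image_after_negative=DEFAULT_P_IMAGE_AFTER_NEGATIVE[scenario]),
        outcomes=OutcomeParams(
            qaly_gain_per_true_positive=calib.gain_per_tp,
            extra_monitoring_years_per_tp=calib.extra_monitoring_years_per_tp,
            avoided_cost_per_skipped_workup=calib.avoided_cost_per_skipped_workup,
        ),
        scenario=scenario,
        country=country,
    )


def load_config(path: str | Path, scenario: str | None = None,
                country: str | None = None,
                test_cost: float | None = None) -> ParameterSet:
    """Load a YAML (or JSON) config file over the base-case defaults.

    Every field present in the file overrides the default for the file's
    (or the caller's) scenario and country; unknown keys are rejected and
    every invariant is re-checked. An empty file reproduces
    :func:`default_parameters` for the flags given by the caller.
    """
    p = Path(path)
    if not p.exists():
        raise ParameterError(str(path), "config file not found")
    text = p.read_text()
    data = (json.loads(text) if p.suffix == ".json" else yaml.safe_load(text)) or {}
    if not isinstance(data, dict):
        raise ParameterError(str(path), "config must be a mapping")
    scenario = data.get("scenario", scenario or "primary")
    country = data.get("country", country or "UK")
    test_cost = data.get("costs", {}).get("test_cost", test_cost)
    base = default_parameters(scenario, country, test_cost)
    merged = _deep_merge(base.to_dict(), data)
    return ParameterSet.from_dict(merged)


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out
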
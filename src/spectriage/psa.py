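"""Probabilistic sensitivity analysis and cost-effectiveness acceptability.

Joint parameter uncertainty is propagated by Monte Carlo: each draw samples
a full parameter set from the uncertainty distributions, runs the whole
arm-pair pipeline, and records the incremental result. The CEAC reports,
per willingness-to-pay λ, the fraction of draws with positive net monetary
benefit.

Distribution families follow standard health-technology-assessment
practice — moment-matched betas for probabilities and the utility weight,
gammas for money-valued quantities — with hyperparameters documented in
``DEFAULT_UNCERTAIN``; the source does not publish its PSA distributions,
so CEAC probability levels are qualitative, not exact reproductions.

Sampling is reproducible: draw *i* uses an independent substream keyed by
(seed, i), so results are independent of evaluation order and identical
seeds give bit-identical CEACs. Comparing test prices with the same seed
uses common random numbers, making price dominance of the CEACs exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cea import IncrementalResult, evaluate, net_monetary_benefit
from .errors import ParameterError
from .parameters import ParameterSet
from .sensitivity import set_parameter


def beta_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Beta shape parameters (α, β) matching a given mean and sd.

    ν = m(1−m)/sd² − 1 must be positive (sd² < m(1−m)); then α = mν,
    β = (1−m)ν, and the resulting distribution has the requested first two
    moments exactly.
    """
    if not 0.0 < mean < 1.0:
        raise ParameterError("mean", f"must be in (0, 1), got {mean}")
    if sd <= 0.0 or sd * sd >= mean * (1.0 - mean):
        raise ParameterError(
            "sd", f"need 0 < sd² < m(1−m); got sd²={sd*sd:g}, "
            f"m(1−m)={mean*(1-mean):g}")
    nu = mean * (1.0 - mean) / (sd * sd) - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Gamma (shape, scale) matching a given mean and sd."""
    if mean <= 0.0 or sd <= 0.0:
        raise ParameterError("mean", "gamma moments must be positive")
    shape = (mean / sd) ** 2
    return shape, sd * sd / mean


@dataclass(frozen=True)
class Dist:
    """One marginal uncertainty distribution.

    kind: "beta" (mean, sd), "gamma" (mean, sd), or "fixed".
    ``sd_scale`` expresses sd as a fraction of the base value (coefficient
    of variation) when ``sd`` is None.
    """

    kind: str
    sd: float | None = None
    sd_scale: float | None = None

    def sample(self, rng: np.random.Generator, base_value: float) -> float:
        if self.kind == "fixed":
            return base_value
        sd = self.sd if self.sd is not None else self.sd_scale * base_value
        if sd == 0.0:
            return base_value
        if self.kind == "beta":
            a, b = beta_from_moments(base_value, sd)
            return float(rng.beta(a, b))
        if self.kind == "gamma":
            shape, scale = gamma_from_moments(base_value, sd)
            return float(rng.gamma(shape, scale))
        raise ParameterError("distribution", f"unknown kind {self.kind!r}")


#: default uncertain parameters, keyed by dotted field path. Test accuracy
#: uses the published SDs; prevalence and money-valued inputs use a 20%
#: coefficient of variation; the natural-history-derived QALY gain g is the
#: most uncertain input and uses cv 30%; the test price is a policy
#: variable and stays fixed.
DEFAULT_UNCERTAIN: dict[str, Dist] = {
    "test.sensitivity": Dist("beta", sd=0.011),
    "test.specificity": Dist("beta", sd=0.019),
    "outcomes.utility": Dist("beta", sd=0.05),
    "cohort.prevalence": Dist("beta", sd_scale=0.2),
    "outcomes.qaly_gain_per_true_positive": Dist("gamma", sd_scale=0.3),
    "outcomes.avoided_cost_per_skipped_workup": Dist("gamma", sd_scale=0.2),
    "costs.monitoring_per_quarter": Dist("gamma", sd_scale=0.2),
}

_MAX_RESAMPLE = 100


@dataclass(frozen=True)
class PSAConfig:
    n_draws: int = 10_000
    seed: int = 0
    distributions: dict[str, Dist] = field(
        default_factory=lambda: dict(DEFAULT_UNCERTAIN))
    lambda_grid: tuple[float, ...] = tuple(float(x) for x in
                                           range(0, 50_001, 1_000))

    def __post_init__(self) -> None:
        if self.n_draws <= 0:
            raise ParameterError("n_draws", "must be positive")
        lam = self.lambda_grid
        if any(x < 0 for x in lam) or any(b >= a for a, b in
                                          zip(lam[1:], lam)):
            raise ParameterError(
                "lambda_grid", "must be non-negative and strictly increasing")


def draw_parameters(config: PSAConfig, base: ParameterSet,
                    draw_index: int) -> ParameterSet:
    """Sampled parameter set for one draw; deterministic in (seed, index).

    A sampled set that violates any parameter invariant is rejected and
    resampled from the same substream (rejection count bounded).
    """
    rng = np.random.default_rng([config.seed, draw_index])
    for _ in range(_MAX_RESAMPLE):
        try:
            params = base
            for path, dist in sorted(config.distributions.items()):
                group, name = path.split(".", 1)
                base_value = getattr(getattr(base, group), name)
                params = params.replace(**{path: dist.sample(rng, base_value)})
            return params
        except ParameterError:
            continue
    raise ParameterError(
        "distributions",
        f"draw {draw_index}: no valid sample after {_MAX_RESAMPLE} attempts")


@dataclass(frozen=True)
class PSAResult:
    config: PSAConfig
    base: ParameterSet
    draws: tuple[ParameterSet, ...]
    results: tuple[IncrementalResult, ...]

    def cloud(self) -> pd.DataFrame:
        """Per-draw incremental outcomes (cost-effectiveness plane cloud)."""
        return pd.DataFrame({
            "draw": range(len(self.results)),
            "delta_cost": [r.delta_cost for r in self.results],
            "delta_qaly": [r.delta_qaly for r in self.results],
        })


def run_psa(config: PSAConfig, base: ParameterSet) -> PSAResult:
    """Full pipeline on every sampled parameter set."""
    base.validate()
    draws = []
    results = []
    for i in range(config.n_draws):
        params = draw_parameters(config, base, i)
        draws.append(params)
        results.append(evaluate(params))
    return PSAResult(config=config, base=base, draws=tuple(draws),
                     results=tuple(results))


@dataclass(frozen=True)
class CEACCurve:
    """Probability cost-effective as a function of willingness to pay."""

    lambdas: tuple[float, ...]
    probabilities: tuple[float, ...]
    n_draws: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lambda": self.lambdas,
                             "probability": self.probabilities,
                             "n_draws": self.n_draws})

    def at(self, lam: float) -> float:
        return self.probabilities[self.lambdas.index(lam)]


def ceac(results, lambda_grid) -> CEACCurve:
    """Fraction of draws with positive NMB at each threshold λ."""
    results = tuple(results)
    if not results:
        raise ParameterError("results", "CEAC needs at least one PSA draw")
    lambdas = tuple(float(x) for x in lambda_grid)
    probs = tuple(
        sum(net_monetary_benefit(r, lam) > 0 for r in results) / len(results)
        for lam in lambdas)
    return CEACCurve(lambdas=lambdas, probabilities=probs,
                     n_draws=len(results))


def ceac_for_test_cost(config: PSAConfig, base: ParameterSet,
                       test_cost: float) -> CEACCurve:
    """CEAC at a given test price, with common random numbers across
    prices (the price itself is never sampled)."""
    priced = set_parameter(base, "test_cost", test_cost)
    res = run_psa(config, priced)
    return ceac(res.results, config.lambda_grid)
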
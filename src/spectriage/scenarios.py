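"""Model-arm construction: confusion-matrix split and pathway routing.

Two arms are compared on an identical cohort: the *with-test* arm inserts
the serum triage test before imaging, the *without-test* comparator is the
current pathway (imaging alone, standard delay D2). In the with-test arm
the cohort first splits by disease status (prevalence), then by test result
(sensitivity/specificity); test-positives are fast-tracked to imaging
(delay D1), test-negatives proceed to imaging at the standard delay with
probability ``p_image_after_negative`` (1.0 in secondary care, 0.5 in
primary care) and otherwise skip the imaging work-up.
"""

from __future__ import annotations

from dataclasses import dataclass

from .outcomes import terminal_payoff
from .parameters import ParameterSet
from .tree import ArmOutcome, Node, rollback


@dataclass(frozen=True)
class ConfusionCounts:
    """Expected (fractional) patient counts by disease status × test result."""

    tp: float
    fp: float
    tn: float
    fn: float

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(cohort, test) -> ConfusionCounts:
    """Expected confusion-matrix counts for a cohort.

    These are expectations, deliberately fractional: the analytic model
    never rounds patients (integer patients live in the microsimulation).
    """
    n, prev = cohort.size, cohort.prevalence
    return ConfusionCounts(
        tp=n * prev * test.sensitivity,
        fn=n * prev * (1.0 - test.sensitivity),
        tn=n * (1.0 - prev) * test.specificity,
        fp=n * (1.0 - prev) * (1.0 - test.specificity),
    )


@dataclass(frozen=True)
class RouteSpec:
    """One terminal route: who reaches it and what happens to them."""

    label: str
    is_diseased: bool
    test_result: str  # "positive" | "negative" | "not_tested"
    delay_class: str | None  # "D1" | "D2" | "D3" | None (no imaging episode)
    receives_imaging: float  # 0.0 or 1.0 at terminal level
    fast_tracked: bool = False
    gains_early_diagnosis: bool = False


# Canonical routes of the with-test arm. Test-positives are fast-tracked
# (D1); true positives gain earlier diagnosis. Test-negatives either follow
# the standard-delay imaging route (D2) or skip imaging entirely.
TP_ROUTE = RouteSpec("diseased/test+/fast-track imaging", True, "positive",
                     "D1", 1.0, fast_tracked=True, gains_early_diagnosis=True)
FN_IMAGED = RouteSpec("diseased/test-/standard imaging", True, "negative",
                      "D2", 1.0)
FN_SKIPPED = RouteSpec("diseased/test-/no imaging", True, "negative",
                       None, 0.0)
FP_ROUTE = RouteSpec("healthy/test+/fast-track imaging", False, "positive",
                     "D1", 1.0, fast_tracked=True)
TN_IMAGED = RouteSpec("healthy/test-/standard imaging", False, "negative",
                      "D2", 1.0)
TN_SKIPPED = RouteSpec("healthy/test-/no imaging", False, "negative",
                       None, 0.0)

# Comparator routes: everyone is imaged at the standard delay.
DISEASED_NO_TEST = RouteSpec("diseased/no test/standard imaging", True,
                             "not_tested", "D2", 1.0)
HEALTHY_NO_TEST = RouteSpec("healthy/no test/standard imaging", False,
                            "not_tested", "D2", 1.0)


def _leaf(route: RouteSpec, params: ParameterSet, with_test: bool) -> Node:
    p = terminal_payoff(route, params, with_test)
    return Node.terminal(route.label, p.cost, p.qaly, meta=route)


def build_arm(params: ParameterSet, with_test: bool) -> Node:
    """Decision tree of one arm, with payoffs attached to terminals."""
    params.validate()
    prev = params.cohort.prevalence
    if not with_test:
        return Node.chance("disease status", [
            (prev, _leaf(DISEASED_NO_TEST, params, False)),
            (1.0 - prev, _leaf(HEALTHY_NO_TEST, params, False)),
        ])
    sens, spec = params.test.sensitivity, params.test.specificity
    p_img = params.pathway.p_image_after_negative
    diseased = Node.chance("diseased: test result", [
        (sens, _leaf(TP_ROUTE, params, True)),
        (1.0 - sens, Node.chance("diseased/test-: imaging?", [
            (p_img, _leaf(FN_IMAGED, params, True)),
            (1.0 - p_img, _leaf(FN_SKIPPED, params, True)),
        ])),
    ])
    healthy = Node.chance("healthy: test result", [
        (1.0 - spec, _leaf(FP_ROUTE, params, True)),
        (spec, Node.chance("healthy/test-: imaging?", [
            (p_img, _leaf(TN_IMAGED, params, True)),
            (1.0 - p_img, _leaf(TN_SKIPPED, params, True)),
        ])),
    ])
    return Node.chance("disease status", [(prev, diseased),
                                          (1.0 - prev, healthy)])


def arm_pair(params: ParameterSet) -> tuple[ArmOutcome, ArmOutcome]:
    """Roll back both arms on the identical cohort and parameters.

    Returns ``(with_test, without_test)`` cohort expectations.
    """
    n = params.cohort.size
    return (rollback(build_arm(params, True), n),
            rollback(build_arm(params, False), n))
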
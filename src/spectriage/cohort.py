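"""Patient-level microsimulation: synthetic cohorts as a Monte-Carlo oracle.

Individual patients are sampled through the same decision tree the analytic
model rolls back: disease status at the stated prevalence, test results via
sensitivity/specificity, routing per the scenario rules, and per-patient
cost/QALY payoffs looked up from the tree's terminal nodes (never
re-derived). Cohort means therefore converge to the analytic expectations,
and any disagreement is attributable to sampling alone.

Integer patients live here; the analytic model works with expected
(fractional) masses and never rounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import ParameterError
from .parameters import ParameterSet
from .scenarios import build_arm
from .tree import ArmOutcome, Node, iter_paths


@dataclass(frozen=True)
class PatientRecord:
    """One simulated patient."""

    id: int
    diseased: bool
    test_result: str  # "positive" | "negative" | "not_tested"
    route: str
    delay_class: str | None
    received_imaging: bool
    cost: float
    qaly: float


@dataclass(frozen=True)
class CohortTable:
    """A simulated cohort, stored columnar; one row per patient."""

    table: pd.DataFrame
    arm: str  # "with_test" | "without_test"
    params: ParameterSet
    seed: int

    @property
    def size(self) -> int:
        return len(self.table)

    def records(self) -> Iterator[PatientRecord]:
        for row in self.table.itertuples(index=False):
            yield PatientRecord(**row._asdict())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


_COLUMNS = ["id", "diseased", "test_result", "route", "delay_class",
            "received_imaging", "cost", "qaly"]


def _paths(root: Node) -> list[tuple[float, Node]]:
    paths = sorted(iter_paths(root), key=lambda pl: pl[1].label)
    total = sum(p for p, _ in paths)
    if abs(total - 1.0) > 1e-9:
        raise ParameterError("tree", f"path probabilities sum to {total}")
    return paths


def _assemble(counts: np.ndarray, leaves: list[Node], rng: np.random.Generator,
              arm: str, params: ParameterSet, seed: int) -> CohortTable:
    n = int(counts.sum())
    route_idx = np.repeat(np.arange(len(leaves)), counts)
    rng.shuffle(route_idx)  # so patient order carries no route structure
    routes = [leaf.meta for leaf in leaves]
    frame = pd.DataFrame({
        "id": np.arange(n),
        "diseased": np.array([r.is_diseased for r in routes])[route_idx],
        "test_result": np.array([r.test_result for r in routes],
                                dtype=object)[route_idx],
        "route": np.array([r.label for r in routes], dtype=object)[route_idx],
        "delay_class": np.array([r.delay_class for r in routes],
                                dtype=object)[route_idx],
        "received_imaging": np.array([r.receives_imaging > 0
                                      for r in routes])[route_idx],
        "cost": np.array([leaf.payoff.cost for leaf in leaves])[route_idx],
        "qaly": np.array([leaf.payoff.qaly for leaf in leaves])[route_idx],
    }, columns=_COLUMNS)
    return CohortTable(table=frame, arm=arm, params=params, seed=seed)


def simulate_cohort(params: ParameterSet, with_test: bool,
                    seed: int) -> CohortTable:
    """Sample one cohort through the built tree; deterministic in ``seed``."""
    params.validate()
    root = build_arm(params, with_test)
    paths = _paths(root)
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(params.cohort.size,
                             [p for p, _ in paths])
    return _assemble(counts, [leaf for _, leaf in paths], rng,
                     "with_test" if with_test else "without_test",
                     params, seed)


def simulate_pair(params: ParameterSet,
                  seed: int) -> tuple[CohortTable, CohortTable]:
    """Paired cohorts with common random numbers on disease status.

    Each patient's disease status is shared between arms; the with-test
    arm then samples the test/routing branches conditionally on status.
    Pairing removes the disease-sampling noise from incremental estimates,
    so paired differences converge to the analytic increments faster than
    independent cohorts.
    """
    params.validate()
    n = params.cohort.size
    prev = params.cohort.prevalence
    rng = np.random.default_rng(seed)
    diseased = rng.random(n) < prev
    n_dis = int(diseased.sum())

    with_root = build_arm(params, True)
    paths = _paths(with_root)
    counts = np.zeros(len(paths), dtype=np.int64)
    for flag, m in ((True, n_dis), (False, n - n_dis)):
        idx = [i for i, (_, leaf) in enumerate(paths)
               if leaf.meta.is_diseased is flag]
        mass = sum(paths[i][0] for i in idx)
        cond = [paths[i][0] / mass for i in idx]
        sub = rng.multinomial(m, cond)
        for j, i in enumerate(idx):
            counts[i] += sub[j]
    with_table = _assemble(counts, [leaf for _, leaf in paths], rng,
                           "with_test", params, seed)

    wo_root = build_arm(params, False)
    wo_paths = _paths(wo_root)
    wo_counts = np.array([n_dis if leaf.meta.is_diseased else n - n_dis
                          for _, leaf in wo_paths], dtype=np.int64)
    wo_table = _assemble(wo_counts, [leaf for _, leaf in wo_paths], rng,
                         "without_test", params, seed)
    return with_table, wo_table


@dataclass(frozen=True)
class EmpiricalSummary:
    """Cohort means in the same shape as an analytic ArmOutcome, with
    Monte-Carlo standard errors."""

    expected_cost: float
    expected_qaly: float
    per_patient_cost: float
    per_patient_qaly: float
    cohort_size: int
    se_cost: float  # standard error of the per-patient mean cost
    se_qaly: float
    route_counts: dict[str, int]

    def agrees_with(self, analytic: ArmOutcome, n_se: float = 4.0) -> bool:
        """Do empirical means lie within ``n_se`` standard errors of the
        analytic expectations (floored to avoid zero-variance division)?"""
        tol_c = n_se * max(self.se_cost, 1e-9)
        tol_q = n_se * max(self.se_qaly, 1e-12)
        return (abs(self.per_patient_cost - analytic.per_patient_cost) <= tol_c
                and abs(self.per_patient_qaly - analytic.per_patient_qaly)
                <= tol_q)


def summarize(cohort: CohortTable) -> EmpiricalSummary:
    """Empirical means, standard errors and per-route counts."""
    t = cohort.table
    n = len(t)
    if n == 0:
        raise ParameterError("cohort", "cannot summarize an empty cohort")
    cost = t["cost"].to_numpy()
    qaly = t["qaly"].to_numpy()
    return EmpiricalSummary(
        expected_cost=float(cost.sum()),
        expected_qaly=float(qaly.sum()),
        per_patient_cost=float(cost.mean()),
        per_patient_qaly=float(qaly.mean()),
        cohort_size=n,
        se_cost=float(cost.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        se_qaly=float(qaly.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        route_counts={k: int(v) for k, v in
                      t["route"].value_counts().items()},
    )
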
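"""Shared fixtures: base-case parameter sets, random-tree and random
parameter-set generators, and the brute-force path-enumeration oracle."""

from __future__ import annotations

import numpy as np
import pytest

from spectriage import (CohortSpec, CostTable, Node, OutcomeParams,
                        ParameterSet, PathwayParams, TestPerformance,
                        default_parameters)


@pytest.fixture(scope="session")
def uk_primary() -> ParameterSet:
    return default_parameters("primary", "UK", 50)


@pytest.fixture(scope="session")
def uk_secondary() -> ParameterSet:
    return default_parameters("secondary", "UK", 50)


def enumerate_expectation(root: Node) -> tuple[float, float]:
    """Independent oracle: expected (cost, qaly) per patient by explicit
    enumeration of every root-to-leaf path (no backward induction)."""
    totals = [0.0, 0.0]

    def walk(node: Node, prob: float) -> None:
        if node.branches is None:
            totals[0] += prob * node.payoff.cost
            totals[1] += prob * node.payoff.qaly
        else:
            for p, child in node.branches:
                walk(child, prob * p)

    walk(root, 1.0)
    return totals[0], totals[1]


@pytest.fixture(scope="session")
def path_enumeration_oracle():
    return enumerate_expectation


def random_tree(rng: np.random.Generator, max_depth: int = 5) -> Node:
    """A random well-formed small tree: 2-3 branches per chance node,
    Dirichlet probabilities, uniform terminal payoffs."""

    def build(depth: int) -> Node:
        if depth >= max_depth or rng.random() < 0.35:
            return Node.terminal(f"leaf{rng.integers(1 << 30)}",
                                 cost=float(rng.uniform(0, 1000)),
                                 qaly=float(rng.uniform(0, 2)))
        k = int(rng.integers(2, 4))
        probs = rng.dirichlet(np.ones(k))
        return Node.chance(f"chance{rng.integers(1 << 30)}",
                           [(float(p), build(depth + 1)) for p in probs])

    root = build(0)
    if root.branches is None:  # ensure at least one chance node
        return Node.chance("root", [(0.5, root),
                                    (0.5, build(max_depth))])
    return root


@pytest.fixture(scope="session")
def random_tree_factory():
    return random_tree


def random_parameter_set(rng: np.random.Generator) -> ParameterSet:
    """A random valid parameter set spanning both scenarios and countries,
    with calibration-scale outcome constants."""
    scenario = rng.choice(["primary", "secondary"])
    country = rng.choice(["UK", "USA"])
    return ParameterSet(
        test=TestPerformance(sensitivity=float(rng.uniform(0.7, 0.99)),
                             specificity=float(rng.uniform(0.7, 0.99))),
        cohort=CohortSpec(size=10_000,
                          prevalence=float(rng.uniform(0.001, 0.1))),
        costs=CostTable.for_country(
            country, test_cost=float(rng.uniform(20, 300)),
            fast_track_premium=float(rng.uniform(0, 100))),
        pathway=PathwayParams(
            p_image_after_negative=float(rng.uniform(0, 1)),
            consultation_addon=float(rng.uniform(0, 60))),
        outcomes=OutcomeParams(
            utility=float(rng.uniform(0.5, 1.0)),
            qaly_gain_per_true_positive=float(rng.uniform(0, 0.5)),
            avoided_cost_per_skipped_workup=float(rng.uniform(0, 400)),
            extra_monitoring_years_per_tp=float(rng.uniform(0, 0.5)),
        ),
        scenario=str(scenario),
        country=str(country),
    )


@pytest.fixture(scope="session")
def random_params_factory():
    return random_parameter_set
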
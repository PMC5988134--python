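"""Generic decision-tree machinery: nodes, validation, expected-value rollback.

The cost-effectiveness model is a one-shot decision tree over a fixed
horizon: chance nodes carry branch probabilities, terminal nodes carry a
(cost, QALY) payoff pair. ``rollback`` computes cohort expectations by
backward induction and records the expected patient mass reaching each
terminal node so cost attributions can be audited.

Payoffs are attached only to terminal nodes (no per-branch incremental
payoffs): the tree is shallow and terminal attribution keeps the audit
trail unambiguous. Probability-sum violations are errors, never silently
renormalised — silent renormalisation hides configuration mistakes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterator, Sequence

from .errors import TreeStructureError

#: tolerance on the sum of branch probabilities at a chance node
PROB_TOL = 1e-9


@dataclass(frozen=True)
class Payoff:
    cost: float
    qaly: float


@dataclass(frozen=True)
class Node:
    """A chance node (with branches) or a terminal node (with a payoff).

    ``meta`` carries arbitrary route metadata (used by the scenario builder
    to tag terminals with their :class:`~spectriage.scenarios.RouteSpec`).
    """

    label: str
    branches: tuple[tuple[float, "Node"], ...] | None = None
    payoff: Payoff | None = None
    meta: Any = None

    @property
    def kind(self) -> str:
        return "terminal" if self.branches is None else "chance"

    @staticmethod
    def chance(label: str, branches: Sequence[tuple[float, "Node"]]) -> "Node":
        return Node(label=label, branches=tuple(branches))

    @staticmethod
    def terminal(label: str, cost: float, qaly: float, meta: Any = None) -> "Node":
        return Node(label=label, payoff=Payoff(cost, qaly), meta=meta)

    def to_dict(self) -> dict:
        """Plain-data serialization for inspection and golden-file tests."""
        if self.kind == "terminal":
            return {"label": self.label,
                    "payoff": {"cost": self.payoff.cost, "qaly": self.payoff.qaly}}
        return {"label": self.label,
                "branches": [{"probability": p, "child": c.to_dict()}
                             for p, c in self.branches]}

    @staticmethod
    def from_dict(data: dict) -> "Node":
        if "payoff" in data:
            return Node.terminal(data["label"], data["payoff"]["cost"],
                                 data["payoff"]["qaly"])
        return Node.chance(
            data["label"],
            [(b["probability"], Node.from_dict(b["child"]))
             for b in data["branches"]])


@dataclass(frozen=True)
class ArmOutcome:
    """Cohort-level expectations of one model arm."""

    expected_cost: float
    expected_qaly: float
    per_patient_cost: float
    per_patient_qaly: float
    cohort_size: float
    terminal_masses: dict[str, float] = field(default_factory=dict)


def validate(root: Node) -> list[str]:
    """Structural findings for a tree; empty list iff well formed.

    Each finding names the node path so configuration mistakes are
    localisable. Findings, not exceptions: callers that want hard failure
    use :func:`rollback`, which refuses invalid trees.
    """
    findings: list[str] = []
    seen: set[int] = set()

    def visit(node: Node, path: str) -> None:
        if id(node) in seen:
            findings.append(f"{path}: node revisited — tree must be acyclic")
            return
        seen.add(id(node))
        if node.branches is not None and node.payoff is not None:
            findings.append(f"{path}: node has both branches and a payoff")
        if node.kind == "terminal":
            if node.payoff is None:
                findings.append(f"{path}: terminal node lacks a payoff")
            return
        if len(node.branches) < 2:
            findings.append(f"{path}: chance node has {len(node.branches)} "
                            "branch(es); at least 2 required")
        total = 0.0
        for i, (p, child) in enumerate(node.branches):
            if not (0.0 <= p <= 1.0):
                findings.append(f"{path}: branch {i} probability {p} "
                                "outside [0, 1]")
            total += p
            visit(child, f"{path}/{child.label}")
        if abs(total - 1.0) > PROB_TOL:
            findings.append(f"{path}: probabilities sum to {total:.12g}")

    visit(root, root.label)
    return findings


def iter_paths(root: Node) -> Iterator[tuple[float, Node]]:
    """Yield (path probability, terminal node) over all root-to-leaf paths."""
    stack: list[tuple[float, Node]] = [(1.0, root)]
    while stack:
        prob, node = stack.pop()
        if node.kind == "terminal":
            yield prob, node
        else:
            for p, child in node.branches:
                stack.append((prob * p, child))


def rollback(root: Node, cohort_size: float) -> ArmOutcome:
    """Expected cost and QALY of a cohort by backward induction.

    Raises :class:`TreeStructureError` if the tree is malformed, quoting
    the first structural finding.
    """
    findings = validate(root)
    if findings:
        raise TreeStructureError(findings[0])

    masses: dict[str, float] = {}

    def expect(node: Node) -> tuple[float, float]:
        if node.kind == "terminal":
            return node.payoff.cost, node.payoff.qaly
        cost = 0.0
        qaly = 0.0
        for p, child in node.branches:
            c, q = expect(child)
            cost += p * c
            qaly += p * q
        return cost, qaly

    per_cost, per_qaly = expect(root)
    for prob, leaf in iter_paths(root):
        masses[leaf.label] = masses.get(leaf.label, 0.0) + prob * cohort_size
    return ArmOutcome(
        expected_cost=per_cost * cohort_size,
        expected_qaly=per_qaly * cohort_size,
        per_patient_cost=per_cost,
        per_patient_qaly=per_qaly,
        cohort_size=cohort_size,
        terminal_masses=masses,
    )
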
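"""Cautious prediction: consequences shared by all admissible labelings.

A statement that holds in every consistent labeling is a prediction.  If a
node takes the same label everywhere the prediction is *strong* (+, -, 0);
if exactly one of the three behaviors is excluded it is *weak*: w+ (never
decreases, both increase and no-change occur), w- (never increases), chg
(always changes, direction open).  When all three behaviors occur the node
is unpredicted ("no").
"""

from __future__ import annotations

import enum
from collections.abc import Iterable, Mapping

from . import _engine
from .model import (
    ExperimentalProfile,
    InconsistentInstanceError,
    InteractionGraph,
    NodeLabel,
    Notion,
)

__all__ = ["PredLabel", "PredictionMap", "classify", "predict"]


class PredLabel(enum.Enum):
    """Prediction outcome for one node."""

    UP = "+"
    DOWN = "-"
    ZERO = "0"
    WEAK_UP = "w+"
    WEAK_DOWN = "w-"
    CHANGE = "chg"
    NO = "no"

    @property
    def token(self) -> str:
        return self.value

    @property
    def is_strong(self) -> bool:
        return self in (PredLabel.UP, PredLabel.DOWN, PredLabel.ZERO)

    @property
    def is_weak(self) -> bool:
        return self in (PredLabel.WEAK_UP, PredLabel.WEAK_DOWN, PredLabel.CHANGE)

    @classmethod
    def from_token(cls, token: str) -> "PredLabel":
        try:
            return cls(token)
        except ValueError:
            raise ValueError(f"unknown prediction token {token!r}")


PredictionMap = Mapping[str, PredLabel]

_CLASSIFY = {
    frozenset({NodeLabel.UP}): PredLabel.UP,
    frozenset({NodeLabel.DOWN}): PredLabel.DOWN,
    frozenset({NodeLabel.ZERO}): PredLabel.ZERO,
    frozenset({NodeLabel.UP, NodeLabel.ZERO}): PredLabel.WEAK_UP,
    frozenset({NodeLabel.DOWN, NodeLabel.ZERO}): PredLabel.WEAK_DOWN,
    frozenset({NodeLabel.UP, NodeLabel.DOWN}): PredLabel.CHANGE,
    frozenset({NodeLabel.UP, NodeLabel.ZERO, NodeLabel.DOWN}): PredLabel.NO,
}


def classify(realized: Iterable[NodeLabel]) -> PredLabel:
    """Map the set of labels a node realizes across admissible labelings to
    its prediction.  An empty set is an error: no admissible behavior."""
    key = frozenset(NodeLabel(v) for v in realized)
    if not key:
        raise ValueError("empty realized-label set: no admissible behavior")
    return _CLASSIFY[key]


def _cautious_consequences(
    inst: _engine.CompiledInstance, mode: str, cost_target: int
) -> dict[str, PredLabel]:
    """Prediction map over leaves of cost ``cost_target``.

    Per node at most two satisfiability queries beyond the shared witness:
    every successful query's full witness feeds the realized sets of all
    nodes, so queries whose answer is already known are skipped.
    """
    bound = cost_target + 1
    first = _engine.find_one(inst, mode, bound=bound)
    if first is None:
        raise InconsistentInstanceError(
            "no admissible labeling; for an inconsistent instance use "
            "predict_under_mcos"
        )
    realized: list[set[int]] = [set() for _ in range(inst.n)]

    def absorb(labels: list[int]) -> None:
        for i, v in enumerate(labels):
            realized[i].add(v)

    absorb(first[0])
    for i, node in enumerate(inst.nodes):
        for v in inst.domains[i]:
            if v in realized[i]:
                continue
            pinned_inst = _engine.CompiledInstance(
                inst.graph,
                inst.profile,
                inst.notion,
                hard_c1=(mode != "scenfit"),
                pinned={node: v},
            )
            hit = _engine.find_one(pinned_inst, mode, bound=bound)
            if hit is not None:
                absorb(hit[0])
    return {
        node: classify(NodeLabel(v) for v in realized[i])
        for i, node in enumerate(inst.nodes)
    }


def predict(
    graph: InteractionGraph,
    profile: ExperimentalProfile,
    notion: Notion = Notion.FSP,
) -> dict[str, PredLabel]:
    """Prediction map over the consistent labelings of the instance.

    Measured nodes are included (their prediction restates or narrows the
    observation); evaluation statistics later restrict to unmeasured nodes.
    Raises :class:`InconsistentInstanceError` when no consistent labeling
    exists — use :func:`signcons.repair.predict_under_mcos` then.
    """
    inst = _engine.CompiledInstance(graph, profile, notion)
    return _cautious_consequences(inst, "hard", cost_target=0)
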
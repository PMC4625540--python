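"""Constraint evaluation and global consistency checking.

Four local constraints relate a total labeling to graph and profile:

* C1 — the labeling must satisfy the (possibly uncertain) observations;
* C2 — a change at a non-input node must be justified by a matching
  influence of some predecessor;
* C3 — a 0-change at a non-input node must be justified: the node receives
  either no nonzero influence or two opposing ones (strong propagation);
* C4 — every change must be *founded*: traceable to an input node along a
  chain of sign-matching influences, which rules out self-justification
  through positive feedback loops.

A graph/profile pair is consistent under a notion (WP, SP, FWP, FSP) iff at
least one total labeling satisfies all of the notion's constraints.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator, Mapping
from typing import NamedTuple, Optional

from . import _engine
from .discretize import allowed_labels
from .model import (
    ExperimentalProfile,
    InteractionGraph,
    NodeLabel,
    Notion,
    TotalLabeling,
    check_total,
    influence,
)

__all__ = [
    "Violation",
    "violations",
    "founded_nodes",
    "is_consistent",
    "enumerate_labelings",
    "exists_labeling",
]

DEFAULT_LABELING_LIMIT = 10**6


class Violation(NamedTuple):
    """A node at which a constraint fails for a given total labeling."""

    node: str
    constraint: str  # one of C1, C2, C3, C4


def founded_nodes(
    graph: InteractionGraph,
    labeling: TotalLabeling,
    inputs: Iterable[str],
) -> frozenset[str]:
    """Least fixpoint of foundedness.

    F contains all inputs; a node i joins F when some edge j -> i has j in F
    and influence equal to the node's own nonzero label.  A changed node
    satisfies C4 exactly when it belongs to F.  The fixpoint is reached in at
    most |V| rounds.
    """
    check_total(graph, labeling)
    founded = set(inputs) & set(graph.nodes)
    queue = list(founded)
    succs: dict[str, list[tuple[str, int]]] = {n: [] for n in graph.nodes}
    for (src, tgt, sign) in graph.edges:
        succs[src].append((tgt, int(sign)))
    while queue:
        j = queue.pop()
        lj = int(labeling[j])
        if lj == 0:
            continue
        for (i, s) in succs[j]:
            if i not in founded and int(labeling[i]) != 0 and lj * s == labeling[i]:
                founded.add(i)
                queue.append(i)
    return frozenset(founded)


def violations(
    graph: InteractionGraph,
    profile: ExperimentalProfile,
    labeling: TotalLabeling,
    notion: Notion = Notion.FSP,
) -> frozenset[Violation]:
    """All constraint violations of ``labeling``; empty iff it is consistent.

    Input nodes are exempt from C2 and C3 and trivially satisfy C4, but
    remain subject to C1 when measured.  C4 is only evaluated for notions
    FWP/FSP and C3 only for SP/FSP.
    """
    check_total(graph, labeling)
    out: set[Violation] = set()
    inputs = profile.inputs
    for node in graph.nodes:
        lab = NodeLabel(labeling[node])
        obs = profile.discrete.get(node)
        if obs is not None and lab not in allowed_labels(obs):
            out.add(Violation(node, "C1"))
        if node in inputs:
            continue
        edges_in = graph.predecessors(node)
        if lab != NodeLabel.ZERO:
            if not any(
                influence(labeling, (j, node, s)) == lab for (j, s) in edges_in
            ):
                out.add(Violation(node, "C2"))
        elif notion.uses_c3:
            infl = [int(labeling[j]) * int(s) for (j, s) in edges_in]
            has_pos = any(w > 0 for w in infl)
            has_neg = any(w < 0 for w in infl)
            if (has_pos or has_neg) and not (has_pos and has_neg):
                out.add(Violation(node, "C3"))
    if notion.uses_c4:
        founded = founded_nodes(graph, labeling, inputs)
        for node in graph.nodes:
            if labeling[node] != NodeLabel.ZERO and node not in founded:
                out.add(Violation(node, "C4"))
    return frozenset(out)


def _decode(inst: _engine.CompiledInstance, labels: list[int]) -> dict[str, NodeLabel]:
    return {node: NodeLabel(labels[i]) for i, node in enumerate(inst.nodes)}


def exists_labeling(
    graph: InteractionGraph,
    profile: ExperimentalProfile,
    notion: Notion = Notion.FSP,
    pinned: Optional[Mapping[str, NodeLabel]] = None,
) -> bool:
    """Is there a consistent labeling extending the partial ``pinned`` map?"""
    inst = _engine.CompiledInstance(
        graph, profile, notion, pinned=dict(pinned) if pinned else None
    )
    return _engine.find_one(inst, "hard") is not None


def is_consistent(
    graph: InteractionGraph,
    profile: ExperimentalProfile,
    notion: Notion = Notion.FSP,
) -> bool:
    """True iff some total labeling satisfies all constraints of ``notion``."""
    return exists_labeling(graph, profile, notion)


def enumerate_labelings(
    graph: InteractionGraph,
    profile: ExperimentalProfile,
    notion: Notion = Notion.FSP,
    limit: Optional[int] = DEFAULT_LABELING_LIMIT,
) -> Iterator[dict[str, NodeLabel]]:
    """Yield every consistent total labeling, without duplicates.

    Order is deterministic: lexicographic over sorted node identifiers with
    value order + < 0 < -.  Labeling counts grow exponentially, so a guard
    raises :class:`LimitExceededError` beyond ``limit`` (pass ``None`` to
    lift the cap).
    """
    inst = _engine.CompiledInstance(graph, profile, notion)
    leaves = _engine.enumerate_leaves(inst, "hard", cost_target=0, limit=limit)
    for labels, _cost, _detail in leaves:
        yield _decode(inst, labels)
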
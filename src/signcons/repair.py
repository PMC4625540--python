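"""Repair of inconsistent instances and prediction under minimal repair.

Two repair semantics:

* **Minimal correction sets (MCoS)** — add a minimum-cardinality set of new
  signed artificial input influences so that graph and profile become
  consistent.  The minimum size divided by the number of observations is the
  *inconsistency index*, a fitness measure of model and data.
* **SCEN-FIT** — keep the network fixed and find labelings satisfying the
  propagation constraints that are closest to the measurements; the minimum
  number of observation mismatches quantifies the disagreement.

MCoS never needs more corrections than SCEN-FIT.  Prediction under minimal
repair takes the consequences shared by all consistent labelings under all
minimum correction sets, favoring none of them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from . import _engine
from .consistency import is_consistent
from .model import (
    ExperimentalProfile,
    InteractionGraph,
    LimitExceededError,
    NodeLabel,
    ObsLabel,
    Notion,
    Sign,
)
from .predict import PredLabel, _cautious_consequences

__all__ = [
    "ARTIFICIAL_PREFIX",
    "is_artificial",
    "RepairSet",
    "RepairResult",
    "apply_repair",
    "repaired_instance",
    "mcos",
    "predict_under_mcos",
    "scenfit",
    "inconsistency_index",
]

#: artificial repair nodes carry this prefix so they can be filtered out
ARTIFICIAL_PREFIX = "repair__"

DEFAULT_MAX_REPAIRS = 32
DEFAULT_LEAF_LIMIT = 10**6

#: a repair set: artificial signed influences (target node, sign) to add
RepairSet = frozenset[tuple[str, Sign]]


def is_artificial(node: str) -> bool:
    return node.startswith(ARTIFICIAL_PREFIX)


def _artificial_id(node: str, sign: Sign) -> str:
    return f"{ARTIFICIAL_PREFIX}{'pos' if int(sign) > 0 else 'neg'}__{node}"


@dataclass(frozen=True)
class RepairResult:
    """Outcome of an MCoS computation.

    ``size`` is the minimum number of added influences; ``sets`` holds every
    minimum-cardinality repair set (in deterministic order) when collected;
    ``index`` is size divided by the number of observations.
    """

    size: int
    sets: tuple[RepairSet, ...]
    index: float


def apply_repair(graph: InteractionGraph, repair: RepairSet) -> InteractionGraph:
    """Graph with one artificial node and signed edge added per repair.

    Each (i, s) adds a fresh node feeding i through an edge of sign s.  The
    artificial nodes are flagged by name (:func:`is_artificial`) so metrics
    and prediction can ignore them; pair with :func:`repaired_instance` to
    also pin their labels to + through the profile.
    """
    new_edges = list(graph.edges)
    for (node, sign) in repair:
        if node not in graph:
            raise KeyError(f"repair target {node!r} is not a node of the graph")
        new_edges.append((_artificial_id(node, sign), node, Sign(sign)))
    return InteractionGraph(new_edges, nodes=graph.nodes)


def repaired_instance(
    graph: InteractionGraph,
    profile: ExperimentalProfile,
    repair: RepairSet,
) -> tuple[InteractionGraph, ExperimentalProfile]:
    """Graph and profile after applying ``repair``.

    Artificial nodes become inputs with a synthetic certain + observation,
    so the added influence is always active and carries its effect through
    the edge sign.
    """
    g2 = apply_repair(graph, repair)
    discrete = dict(profile.discrete)
    inputs = set(profile.inputs)
    for (node, sign) in repair:
        art = _artificial_id(node, sign)
        discrete[art] = ObsLabel.UP
        inputs.add(art)
    raw = None if profile.raw is None else dict(profile.raw)
    if raw is not None:
        # keep the raw/discrete domains aligned; the synthetic observation
        # has no measured value, so drop raw rather than invent one
        raw = None
    return g2, ExperimentalProfile(discrete=discrete, inputs=inputs, raw=raw)


def _repair_sets_of_leaf(
    inst: _engine.CompiledInstance, labels: list[int], detail: tuple
) -> list[RepairSet]:
    """All minimum repair sets certified by one optimal labeling.

    C2 violations force (node, label); C3 violations force the opposing
    sign; every source SCC of the unfounded subgraph contributes a free
    choice among its members, each repaired with the member's own label.
    """
    c2, c3, sources = detail
    mandatory = [(inst.nodes[i], Sign(labels[i])) for i in c2]
    mandatory += [(inst.nodes[i], Sign(s)) for (i, s) in c3]
    if not sources:
        return [frozenset(mandatory)]
    out = []
    for combo in itertools.product(*sources):
        extra = [(inst.nodes[i], Sign(labels[i])) for i in combo]
        out.append(frozenset(mandatory + extra))
    return out


def mcos(
    graph: InteractionGraph,
    profile: ExperimentalProfile,
    notion: Notion = Notion.FSP,
    *,
    max_size: int = DEFAULT_MAX_REPAIRS,
    collect_sets: bool = True,
    leaf_limit: int = DEFAULT_LEAF_LIMIT,
) -> RepairResult:
    """Minimum correction sets: size, (optionally) all sets, and the index.

    The search minimizes, over C1-admissible labelings, the number of
    artificial influences the labeling forces; iterative deepening
    guarantees the first feasible cost is the minimum.  Every inconsistency
    is repairable this way, but a hard cap ``max_size`` guards runaway
    searches and raises :class:`LimitExceededError`.
    """
    n_obs = len(profile.measured & set(graph.nodes))

    def make_index(size: int) -> float:
        return 0.0 if size == 0 else size / n_obs

    if is_consistent(graph, profile, notion):
        return RepairResult(0, (frozenset(),), 0.0)
    inst = _engine.CompiledInstance(graph, profile, notion)
    best = _engine.minimize(inst, "mcos", max_cost=max_size, min_cost=1)
    if best is None:
        raise LimitExceededError(
            f"no correction set of size <= {max_size} found (cap reached)"
        )
    if not collect_sets:
        return RepairResult(best, (), make_index(best))
    sets: set[RepairSet] = set()
    for labels, _cost, detail in _engine.enumerate_leaves(
        inst, "mcos", cost_target=best, limit=leaf_limit
    ):
        sets.update(_repair_sets_of_leaf(inst, labels, detail))
    ordered = tuple(
        sorted(sets, key=lambda r: sorted((n, int(s)) for (n, s) in r))
    )
    return RepairResult(best, ordered, make_index(best))


def inconsistency_index(
    graph: InteractionGraph,
    profile: ExperimentalProfile,
    notion: Notion = Notion.FSP,
    *,
    max_size: int = DEFAULT_MAX_REPAIRS,
) -> float:
    """Minimum correction set size divided by the number of observations."""
    if not (profile.measured & set(graph.nodes)):
        raise ValueError("inconsistency index undefined: no observations")
    return mcos(
        graph, profile, notion, max_size=max_size, collect_sets=False
    ).index


def predict_under_mcos(
    graph: InteractionGraph,
    profile: ExperimentalProfile,
    notion: Notion = Notion.FSP,
    *,
    max_size: int = DEFAULT_MAX_REPAIRS,
) -> dict[str, PredLabel]:
    """Prediction map under all minimum correction sets.

    A labeling is admissible iff it is consistent under *some* minimum
    repair set, which is exactly the set of labelings whose minimal repair
    cost equals the optimum — so no repair-set enumeration is needed.
    Degenerates to :func:`signcons.predict.predict` on consistent
    instances.  Artificial nodes never appear in the map.
    """
    inst = _engine.CompiledInstance(graph, profile, notion)
    if _engine.find_one(inst, "hard") is not None:
        # consistent: the minimum repair is empty and the admissible
        # labelings are exactly the consistent ones
        return _cautious_consequences(inst, "hard", cost_target=0)
    best = _engine.minimize(inst, "mcos", max_cost=max_size, min_cost=1)
    if best is None:
        raise LimitExceededError(
            f"no correction set of size <= {max_size} found (cap reached)"
        )
    return _cautious_consequences(inst, "mcos", cost_target=best)


def scenfit(
    graph: InteractionGraph,
    profile: ExperimentalProfile,
    notion: Notion = Notion.FSP,
    *,
    leaf_limit: int = DEFAULT_LEAF_LIMIT,
) -> tuple[int, tuple[dict[str, NodeLabel], ...]]:
    """Minimum number of observation corrections, with all witnesses.

    Labelings must satisfy the propagation constraints (C2, and C3/C4 per
    notion) for every node; the cost of a labeling is the number of measured
    nodes whose label falls outside the observation's admitted set (unit
    cost, uncertain observations admitting two labels).  Returns the
    minimum cost and all cost-minimal labelings in lexicographic order;
    cost 0 iff the instance is consistent.
    """
    inst = _engine.CompiledInstance(graph, profile, notion, hard_c1=False)
    n_obs = len(profile.measured & set(graph.nodes))
    best = _engine.minimize(inst, "scenfit", max_cost=n_obs)
    if best is None:  # pragma: no cover - cost can never exceed n_obs
        raise LimitExceededError("scenfit search failed to find any labeling")
    witnesses = tuple(
        {node: NodeLabel(labels[i]) for i, node in enumerate(inst.nodes)}
        for labels, _cost, _detail in _engine.enumerate_leaves(
            inst, "scenfit", cost_target=best, limit=leaf_limit
        )
    )
    return best, witnesses
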
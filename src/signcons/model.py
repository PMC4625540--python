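"""Domain types for sign-consistency analysis of interaction graphs.

An interaction graph (IG) is a signed directed graph (V, E, sigma): nodes are
molecular species, an edge j -> i with sign + (-) means that a change in j
tends to increase (decrease) the level of i.  The IG is confronted with an
*experimental profile* from a steady-state shift experiment: a set of measured
species with discretized observations over a five-valued alphabet, and a set
of *input* nodes whose changes are externally imposed and therefore need no
explanation by the network.

Candidate system behaviors are *total labelings* mapping every node to one of
{+, 0, -} (increase, no change, decrease); the consistency machinery in
:mod:`signcons.consistency` decides which labelings are admissible.
"""

from __future__ import annotations

import enum
import logging
import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

logger = logging.getLogger(__name__)

__all__ = [
    "Sign",
    "NodeLabel",
    "ObsLabel",
    "Edge",
    "InteractionGraph",
    "ExperimentalProfile",
    "DiscretizationThresholds",
    "DEFAULT_THRESHOLDS",
    "Notion",
    "TotalLabeling",
    "influence",
    "check_total",
    "reconcile",
    "SignConsError",
    "ParseError",
    "InconsistentInstanceError",
    "LimitExceededError",
]


class SignConsError(Exception):
    """Base class for errors raised by signcons."""


class ParseError(SignConsError):
    """Malformed input file (carries the offending line number)."""


class InconsistentInstanceError(SignConsError):
    """Raised when an operation requires a consistent graph/profile pair."""


class LimitExceededError(SignConsError):
    """An enumeration or search exceeded its configured cap."""


class Sign(enum.IntEnum):
    """Edge sign: activation (+1) or inhibition (-1)."""

    PLUS = 1
    MINUS = -1

    @classmethod
    def from_token(cls, token: str) -> "Sign":
        try:
            return _SIGN_TOKENS[token]
        except KeyError:
            raise ValueError(f"unknown sign token {token!r} (expected '+' or '-')")

    @property
    def token(self) -> str:
        return "+" if self is Sign.PLUS else "-"


_SIGN_TOKENS = {"+": Sign.PLUS, "-": Sign.MINUS}


class NodeLabel(enum.IntEnum):
    """Label of a node in a total labeling: increase, no change, decrease."""

    UP = 1
    ZERO = 0
    DOWN = -1

    @classmethod
    def from_token(cls, token: str) -> "NodeLabel":
        try:
            return _NODE_TOKENS[token]
        except KeyError:
            raise ValueError(f"unknown node label token {token!r}")

    @property
    def token(self) -> str:
        return {1: "+", 0: "0", -1: "-"}[int(self)]


_NODE_TOKENS = {"+": NodeLabel.UP, "0": NodeLabel.ZERO, "-": NodeLabel.DOWN}


class ObsLabel(enum.Enum):
    """Discretized observation over the five-valued alphabet.

    ``UP``/``DOWN``/``ZERO`` are certain calls; ``UNCERTAIN_UP`` (an increase
    that may also be a no-change) and ``UNCERTAIN_DOWN`` are the uncertain
    bands of the discretization.  Serialized as ``+ u+ 0 u- -``.
    """

    UP = "+"
    UNCERTAIN_UP = "u+"
    ZERO = "0"
    UNCERTAIN_DOWN = "u-"
    DOWN = "-"

    @classmethod
    def from_token(cls, token: str) -> "ObsLabel":
        try:
            return cls(token)
        except ValueError:
            raise ValueError(f"unknown observation token {token!r}")

    @property
    def token(self) -> str:
        return self.value

    @property
    def is_certain(self) -> bool:
        return self in (ObsLabel.UP, ObsLabel.ZERO, ObsLabel.DOWN)

    @property
    def certain_label(self) -> Optional[NodeLabel]:
        """The NodeLabel of a certain observation, else ``None``."""
        return _CERTAIN.get(self)


_CERTAIN = {
    ObsLabel.UP: NodeLabel.UP,
    ObsLabel.ZERO: NodeLabel.ZERO,
    ObsLabel.DOWN: NodeLabel.DOWN,
}

#: rank for the natural order  -  <  u-  <  0  <  u+  <  +
OBS_ORDER = {
    ObsLabel.DOWN: 0,
    ObsLabel.UNCERTAIN_DOWN: 1,
    ObsLabel.ZERO: 2,
    ObsLabel.UNCERTAIN_UP: 3,
    ObsLabel.UP: 4,
}


class Edge(NamedTuple):
    source: str
    target: str
    sign: Sign


def _check_node_id(node: str) -> None:
    if not isinstance(node, str) or not node:
        raise ValueError(f"node identifier must be a non-empty string, got {node!r}")
    if "\t" in node or "\n" in node:
        raise ValueError(f"node identifier contains tab/newline: {node!r}")


class InteractionGraph:
    """Signed directed graph (V, E, sigma).

    Parallel edges between the same endpoints with *opposite* signs are kept
    (this is how unsigned interactions are encoded); exact duplicates are
    collapsed.  Self-loops are permitted.  Node identifiers are case-sensitive
    opaque strings.
    """

    __slots__ = ("_nodes", "_edges", "_preds", "_hash")

    def __init__(
        self,
        edges: Iterable[tuple[str, str, Sign] | Edge] = (),
        nodes: Iterable[str] = (),
    ):
        edge_set = set()
        node_set = set(nodes)
        for n in node_set:
            _check_node_id(n)
        for e in edges:
            src, tgt, sign = e
            _check_node_id(src)
            _check_node_id(tgt)
            edge_set.add(Edge(src, tgt, Sign(sign)))
            node_set.add(src)
            node_set.add(tgt)
        self._nodes: tuple[str, ...] = tuple(sorted(node_set))
        self._edges: tuple[Edge, ...] = tuple(sorted(edge_set))
        preds: dict[str, list[tuple[str, Sign]]] = {n: [] for n in self._nodes}
        for e in self._edges:
            preds[e.target].append((e.source, e.sign))
        self._preds = {n: tuple(v) for n, v in preds.items()}
        self._hash: Optional[int] = None

    @property
    def nodes(self) -> tuple[str, ...]:
        return self._nodes

    @property
    def edges(self) -> tuple[Edge, ...]:
        return self._edges

    def __contains__(self, node: str) -> bool:
        return node in self._preds

    def __len__(self) -> int:
        return len(self._nodes)

    def predecessors(self, node: str) -> tuple[tuple[str, Sign], ...]:
        """Incoming edges of ``node`` as (source, sign) pairs, sorted."""
        try:
            return self._preds[node]
        except KeyError:
            raise KeyError(f"unknown node {node!r}")

    def predecessor_free_nodes(self) -> frozenset[str]:
        return frozenset(n for n in self._nodes if not self._preds[n])

    def __eq__(self, other) -> bool:
        if not isinstance(other, InteractionGraph):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    def __hash__(self) -> int:
        if self._hash is None:
            self._hash = hash((self._nodes, self._edges))
        return self._hash

    def __repr__(self) -> str:
        return f"InteractionGraph(|V|={len(self._nodes)}, |E|={len(self._edges)})"


#: A total labeling is any mapping from node id to NodeLabel that covers
#: every node of the associated graph (checked by :func:`check_total`).
TotalLabeling = Mapping[str, NodeLabel]


def check_total(graph: InteractionGraph, labeling: TotalLabeling) -> None:
    """Raise ``ValueError`` unless ``labeling`` assigns every graph node."""
    missing = [n for n in graph.nodes if n not in labeling]
    if missing:
        raise ValueError(f"labeling is not total; missing nodes: {missing[:5]}")


def influence(labeling: TotalLabeling, edge: tuple[str, str, Sign]) -> NodeLabel:
    """Influence of an edge's source on its target: the product mu_t(j)*sigma.

    Sign arithmetic: (+)*(+) = +, (+)*(-) = -, 0 absorbs.
    """
    src, _tgt, sign = edge
    try:
        lab = labeling[src]
    except KeyError:
        raise KeyError(f"labeling does not cover source node {src!r}")
    return NodeLabel(int(lab) * int(sign))


@dataclass(frozen=True)
class DiscretizationThresholds:
    """Condition-dependent thresholds t1 <= t2 < 0 < t3 <= t4.

    The bands (t1, t2] and [t3, t4) are the uncertain observations; equal
    thresholds (t1 == t2 or t3 == t4) are legal and make the corresponding
    uncertain band empty.
    """

    t1: float
    t2: float
    t3: float
    t4: float

    def __post_init__(self):
        vals = (self.t1, self.t2, self.t3, self.t4)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"thresholds must be finite, got {vals}")
        if not (self.t1 <= self.t2 < 0 < self.t3 <= self.t4):
            raise ValueError(
                f"thresholds must satisfy t1 <= t2 < 0 < t3 <= t4, got {vals}"
            )


#: Typical thresholds for microarray log-ratios.
DEFAULT_THRESHOLDS = DiscretizationThresholds(-2.0, -0.01, 0.01, 2.0)


@dataclass(frozen=True)
class ExperimentalProfile:
    """Experimental profile (S, I, mu) of a steady-state shift experiment.

    ``discrete`` maps each measured node to its five-valued observation;
    ``inputs`` are the perturbed (or predecessor-free) nodes whose changes
    are trivially explained.  An input need not be measured: its label is
    then unconstrained.  ``raw`` optionally keeps the real-valued
    measurements (log-ratio units) the observations were discretized from.
    """

    discrete: Mapping[str, ObsLabel] = field(default_factory=dict)
    inputs: frozenset[str] = frozenset()
    raw: Optional[Mapping[str, float]] = None

    def __post_init__(self):
        object.__setattr__(self, "discrete", dict(self.discrete))
        object.__setattr__(self, "inputs", frozenset(self.inputs))
        for n, o in self.discrete.items():
            _check_node_id(n)
            if not isinstance(o, ObsLabel):
                raise TypeError(f"observation for {n!r} is not an ObsLabel: {o!r}")
        for n in self.inputs:
            _check_node_id(n)
        if self.raw is not None:
            object.__setattr__(self, "raw", dict(self.raw))
            if set(self.raw) != set(self.discrete):
                raise ValueError("raw measurement domain must equal the measured set")

    @property
    def measured(self) -> frozenset[str]:
        return frozenset(self.discrete)

    def restricted_to(self, nodes: Iterable[str]) -> "ExperimentalProfile":
        """Profile with observations and inputs restricted to ``nodes``."""
        keep = set(nodes)
        discrete = {n: o for n, o in self.discrete.items() if n in keep}
        raw = (
            {n: v for n, v in self.raw.items() if n in keep}
            if self.raw is not None
            else None
        )
        return ExperimentalProfile(
            discrete=discrete, inputs=self.inputs & keep, raw=raw
        )

    def subset(self, nodes: Iterable[str]) -> "ExperimentalProfile":
        """Profile keeping only the observations of ``nodes``; inputs unchanged."""
        keep = set(nodes)
        unknown = keep - set(self.discrete)
        if unknown:
            raise KeyError(f"not measured: {sorted(unknown)[:5]}")
        discrete = {n: self.discrete[n] for n in keep}
        raw = {n: self.raw[n] for n in keep} if self.raw is not None else None
        return ExperimentalProfile(discrete=discrete, inputs=self.inputs, raw=raw)


def reconcile(
    graph: InteractionGraph, profile: ExperimentalProfile
) -> ExperimentalProfile:
    """Drop observations and inputs that name nodes absent from the graph.

    High-throughput profiles routinely cover many species outside the network
    model (the tool must tolerate partial overlap), so this is a warning, not
    an error; the number of dropped observations is logged.
    """
    in_graph = set(graph.nodes)
    dropped = len(set(profile.discrete) - in_graph)
    dropped_inputs = len(profile.inputs - in_graph)
    if dropped or dropped_inputs:
        logger.warning(
            "reconciliation dropped %d observation(s) and %d input(s) "
            "not present among the %d graph nodes",
            dropped,
            dropped_inputs,
            len(graph),
        )
    return profile.restricted_to(in_graph)


class Notion(enum.Enum):
    """Global consistency notion: which local constraints must hold.

    * WP  (weak propagation): observations (C1) + every change justified by a
      predecessor change (C2).
    * SP  (strong propagation): WP + 0-changes justified (C3): a node may be
      unchanged only if it receives no nonzero influence or two opposing ones.
    * FWP (founded weak propagation): WP + foundedness (C4): every change must
      be traceable to an input along sign-matching influences, which filters
      self-justification through positive feedback loops.
    * FSP (founded strong propagation): all four constraints.
    """

    WP = "WP"
    SP = "SP"
    FWP = "FWP"
    FSP = "FSP"

    @property
    def uses_c3(self) -> bool:
        return self in (Notion.SP, Notion.FSP)

    @property
    def uses_c4(self) -> bool:
        return self in (Notion.FWP, Notion.FSP)

    @property
    def constraints(self) -> frozenset[str]:
        cs = {"C1", "C2"}
        if self.uses_c3:
            cs.add("C3")
        if self.uses_c4:
            cs.add("C4")
        return frozenset(cs)
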
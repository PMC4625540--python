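"""Synthetic instances with a known hidden consistent labeling.

The generator emulates a steady-state shift experiment: a random signed
digraph, input nodes (predecessor-free ones, as in stress experiments where
the true perturbation targets are unknown), a hidden total labeling that is
consistent with the chosen notion and nonzero at the perturbed inputs, and a
partial, optionally softened or corrupted observation of that labeling.
Because the hidden labeling is a consistency witness, noiseless profiles are
consistent by construction and every sound prediction must agree with it.

The hidden labeling is sampled through the consistency engine with
randomized branching (rather than forward simulation), so it is a valid
witness under any notion including FSP.  A single integer seed derives all
sub-seeds through ``numpy.random.default_rng([seed, stream])`` with fixed
stream numbers (0 graph topology, 1 input perturbation and labeling search,
2 observation sampling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import _engine
from .model import (
    ExperimentalProfile,
    InteractionGraph,
    NodeLabel,
    Notion,
    ObsLabel,
    Sign,
)

__all__ = [
    "SynthConfig",
    "random_graph",
    "sample_instance",
    "random_test_instance",
    "builtin_instances",
]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    Defaults mirror the proportions of a curated transcriptional network
    confronted with microarray profiles, scaled to desk size: 2.6 edges per
    node, 85 % of nodes observed, about a third of edges inhibitory, a tenth
    of the observations falling in the uncertain discretization bands, and
    no observation noise.
    """

    n_nodes: int = 30
    n_edges: int = 78
    p_negative: float = 0.35
    p_input: float = 0.0
    frac_observed: float = 0.85
    frac_uncertain: float = 0.10
    noise_flips: float = 0.0
    notion: Notion = Notion.FSP
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if self.n_edges < 0:
            raise ValueError("n_edges must be >= 0")
        if self.n_edges > self.n_nodes**2:
            raise ValueError(
                f"n_edges={self.n_edges} exceeds n_nodes^2={self.n_nodes ** 2}"
            )
        for name in ("p_negative", "p_input", "frac_observed", "frac_uncertain",
                     "noise_flips"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_uncertain + self.noise_flips > 1.0:
            raise ValueError("frac_uncertain + noise_flips must not exceed 1")


def _node_name(i: int) -> str:
    return f"n{i:04d}"


def random_graph(cfg: SynthConfig) -> InteractionGraph:
    """Simple signed digraph: ``n_edges`` distinct (source, target) pairs
    (self-loops allowed), each inhibitory with probability ``p_negative``."""
    rng = np.random.default_rng([cfg.seed, 0])
    n = cfg.n_nodes
    pair_ids = rng.choice(n * n, size=cfg.n_edges, replace=False)
    edges = []
    for pid in sorted(int(p) for p in pair_ids):
        src, tgt = divmod(pid, n)
        sign = Sign.MINUS if rng.random() < cfg.p_negative else Sign.PLUS
        edges.append((_node_name(src), _node_name(tgt), sign))
    return InteractionGraph(edges, nodes=[_node_name(i) for i in range(n)])


_SOFTEN = {
    NodeLabel.UP: ObsLabel.UNCERTAIN_UP,
    NodeLabel.DOWN: ObsLabel.UNCERTAIN_DOWN,
}
_CERTAIN_OBS = {
    NodeLabel.UP: ObsLabel.UP,
    NodeLabel.ZERO: ObsLabel.ZERO,
    NodeLabel.DOWN: ObsLabel.DOWN,
}


def sample_instance(
    cfg: SynthConfig,
) -> tuple[InteractionGraph, dict[str, NodeLabel], ExperimentalProfile]:
    """Graph, hidden consistent labeling, and observed profile.

    Inputs are the predecessor-free nodes plus extra nodes with probability
    ``p_input``; each input is perturbed to a random nonzero label, and the
    remaining labels come from a randomized consistency search so the hidden
    labeling is a witness under ``cfg.notion``.  The profile observes
    ``ceil(frac_observed * |V|)`` nodes: the hidden label, softened to the
    matching uncertain observation with probability ``frac_uncertain`` or
    flipped to a different certain label with probability ``noise_flips``.
    """
    graph = random_graph(cfg)
    rng = np.random.default_rng([cfg.seed, 1])
    inputs = set(graph.predecessor_free_nodes())
    for node in graph.nodes:
        if node not in inputs and rng.random() < cfg.p_input:
            inputs.add(node)
    if not inputs:
        # a steady-state shift experiment perturbs something: when every
        # node has predecessors, designate one perturbed input explicitly
        inputs.add(str(rng.choice(graph.nodes)))

    hidden = None
    for _attempt in range(20):  # guarded resample; pinned inputs make the
        # instance satisfiable, so the first attempt should succeed
        pinned = {
            node: NodeLabel(int(rng.choice([1, -1]))) for node in sorted(inputs)
        }
        inst = _engine.CompiledInstance(
            graph,
            ExperimentalProfile(discrete={}, inputs=inputs),
            cfg.notion,
            pinned=pinned,
            forward_order=True,
        )
        hit = _engine.find_one(inst, "hard", rng=rng, founded_prefix=True)
        if hit is not None:
            hidden = {
                node: NodeLabel(hit[0][i]) for i, node in enumerate(inst.nodes)
            }
            break
    if hidden is None:  # pragma: no cover - defensive
        raise RuntimeError("could not sample a consistent hidden labeling")

    obs_rng = np.random.default_rng([cfg.seed, 2])
    n_obs = math.ceil(cfg.frac_observed * len(graph))
    observed = sorted(
        str(x) for x in obs_rng.choice(graph.nodes, size=n_obs, replace=False)
    )
    discrete: dict[str, ObsLabel] = {}
    for node in observed:
        value = hidden[node]
        r = obs_rng.random()
        if r < cfg.frac_uncertain:
            if value is NodeLabel.ZERO:
                # 0 has no dedicated uncertain band; either band contains it
                discrete[node] = (
                    ObsLabel.UNCERTAIN_UP
                    if obs_rng.random() < 0.5
                    else ObsLabel.UNCERTAIN_DOWN
                )
            else:
                discrete[node] = _SOFTEN[value]
        elif r < cfg.frac_uncertain + cfg.noise_flips:
            others = [v for v in NodeLabel if v is not value]
            discrete[node] = _CERTAIN_OBS[others[int(obs_rng.integers(2))]]
        else:
            discrete[node] = _CERTAIN_OBS[value]
    profile = ExperimentalProfile(discrete=discrete, inputs=frozenset(inputs))
    return graph, hidden, profile


def random_test_instance(
    seed: int, max_nodes: int = 8
) -> tuple[InteractionGraph, ExperimentalProfile]:
    """Small random instance with arbitrary observations and inputs.

    Unlike :func:`sample_instance` there is no hidden consistent labeling:
    observations are drawn uniformly, so the instance may be inconsistent.
    This is the distribution used to cross-check the search engine against
    the exhaustive reference implementations on enumerable sizes.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, max_nodes + 1))
    n_edges = int(rng.integers(0, min(n * n, 2 * n) + 1))
    graph = random_graph(
        SynthConfig(n_nodes=n, n_edges=n_edges, p_negative=0.4, seed=seed)
    )
    nodes = list(graph.nodes)
    n_inputs = int(rng.integers(0, n + 1)) // 2
    inputs = {str(x) for x in rng.choice(nodes, size=n_inputs, replace=False)}
    n_obs = int(rng.integers(1, n + 1))
    obs_nodes = [str(x) for x in rng.choice(nodes, size=n_obs, replace=False)]
    obs_vals = rng.choice(list(ObsLabel), size=n_obs)
    profile = ExperimentalProfile(
        discrete=dict(zip(obs_nodes, obs_vals)), inputs=inputs
    )
    return graph, profile


def builtin_instances() -> dict[str, tuple[InteractionGraph, ExperimentalProfile]]:
    """Small hand-built instances used throughout the tests and docs.

    * ``g1`` — a single activation A -> B with both nodes increased:
      consistent under every notion.
    * ``g2`` — a two-node negative feedback loop with both nodes observed
      increased and no inputs: locally consistent at each node but globally
      inconsistent.
    * ``g3`` — a chain with a two-node positive loop (B <-> C): the increase
      of D can be explained by self-activation of the loop, which
      foundedness rejects when the only input A is unchanged.
    * ``g4`` — one input C activating both A and B, observed to change in
      opposite directions: inconsistent, with two singleton correction sets.
    * ``posloop`` — an eight-node network containing a positive feedback
      loop between E and F, inputs A and D increased and H measured
      unchanged.  A synthetic reconstruction assembled to exhibit the
      canonical behavior of the four notions: predictions sharpen from weak
      to strong as constraints are added, and foundedness excludes the
      labelings where E and F sustain each other's decrease.
    """
    P, M = Sign.PLUS, Sign.MINUS
    o = ObsLabel
    out: dict[str, tuple[InteractionGraph, ExperimentalProfile]] = {}
    out["g1"] = (
        InteractionGraph([("A", "B", P)]),
        ExperimentalProfile(discrete={"A": o.UP, "B": o.UP}, inputs={"A"}),
    )
    out["g2"] = (
        InteractionGraph([("B", "A", P), ("A", "B", M)]),
        ExperimentalProfile(discrete={"A": o.UP, "B": o.UP}),
    )
    out["g3"] = (
        InteractionGraph(
            [("A", "B", P), ("B", "C", P), ("C", "B", P), ("C", "D", P)]
        ),
        ExperimentalProfile(discrete={"A": o.ZERO, "D": o.UP}, inputs={"A"}),
    )
    out["g4"] = (
        InteractionGraph([("C", "A", P), ("C", "B", P)]),
        ExperimentalProfile(discrete={"A": o.UP, "B": o.DOWN}, inputs={"C"}),
    )
    out["posloop"] = (
        InteractionGraph(
            [
                ("A", "B", P),
                ("D", "E", P),
                ("E", "F", P),
                ("F", "E", P),
                ("E", "C", P),
                ("G", "C", P),
                ("C", "G", P),
                ("E", "G", M),
                ("G", "H", P),
            ]
        ),
        ExperimentalProfile(
            discrete={"A": o.UP, "D": o.UP, "H": o.ZERO}, inputs={"A", "D"}
        ),
    )
    return out
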
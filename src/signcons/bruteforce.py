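"""Exhaustive reference implementations for small instances.

Everything here enumerates all 3^|V| total labelings with vectorized numpy
operations and evaluates the constraint definitions directly — no search,
no propagation, no pruning.  It exists to validate the branch-and-bound
engine: on any instance small enough to enumerate, the engine must agree
with these functions exactly (consistency verdict, labeling sets,
prediction maps, correction-set sizes and members).  Keep it independent of
:mod:`signcons._engine`; slowness is the point.
"""

from __future__ import annotations

import itertools
from collections.abc import Iterable

import numpy as np

from .discretize import allowed_labels
from .model import (
    ExperimentalProfile,
    InteractionGraph,
    NodeLabel,
    Notion,
    Sign,
)
from .predict import PredLabel, classify

__all__ = [
    "all_labelings",
    "consistent_mask",
    "is_consistent_bf",
    "enumerate_labelings_bf",
    "predict_bf",
    "mcos_bf",
    "scenfit_bf",
]

_VALUES = np.array([1, 0, -1], dtype=np.int8)


def all_labelings(n: int) -> np.ndarray:
    """(3^n, n) array of every total labeling, lexicographic in + < 0 < -."""
    grids = np.meshgrid(*([_VALUES] * n), indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def consistent_mask(
    graph: InteractionGraph,
    profile: ExperimentalProfile,
    notion: Notion,
    repairs: Iterable[tuple[str, Sign]] = (),
    check_c1: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """All labelings and the boolean mask of the consistent ones.

    ``repairs`` are artificial always-active influences (node, sign): they
    justify a matching change (C2), contribute their sign to the influence
    multiset (C3), and found a matching change directly (C4).
    """
    nodes = list(graph.nodes)
    idx = {node: i for i, node in enumerate(nodes)}
    n = len(nodes)
    L = all_labelings(n)
    ok = np.ones(len(L), dtype=bool)
    rep: dict[int, list[int]] = {}
    for (node, sign) in repairs:
        rep.setdefault(idx[node], []).append(int(sign))

    if check_c1:
        for node, obs in profile.discrete.items():
            if node not in idx:
                continue
            allowed = [int(v) for v in allowed_labels(obs)]
            ok &= np.isin(L[:, idx[node]], allowed)

    inputs = {idx[node] for node in profile.inputs if node in idx}
    for i in range(n):
        if i in inputs:
            continue
        v = L[:, i]
        edges_in = [(idx[j], int(s)) for (j, s) in graph.predecessors(nodes[i])]
        justified = np.zeros(len(L), dtype=bool)
        for (j, s) in edges_in:
            justified |= L[:, j] * s == v
        for s in rep.get(i, ()):
            justified |= v == s
        ok &= (v == 0) | justified
        if notion.uses_c3:
            has_pos = np.zeros(len(L), dtype=bool)
            has_neg = np.zeros(len(L), dtype=bool)
            for (j, s) in edges_in:
                infl = L[:, j] * s
                has_pos |= infl == 1
                has_neg |= infl == -1
            for s in rep.get(i, ()):
                has_pos |= s == 1
                has_neg |= s == -1
            nz = has_pos | has_neg
            ok &= (v != 0) | ~nz | (has_pos & has_neg)

    if notion.uses_c4:
        founded = np.zeros((len(L), n), dtype=bool)
        for i in inputs:
            founded[:, i] = True
        for i, signs in rep.items():
            for s in signs:
                founded[:, i] |= L[:, i] == s
        for _round in range(n):
            prev = founded.copy()
            for i in range(n):
                v = L[:, i]
                for (j, s) in [
                    (idx[j], int(s)) for (j, s) in graph.predecessors(nodes[i])
                ]:
                    founded[:, i] |= prev[:, j] & (L[:, j] * s == v) & (v != 0)
            if np.array_equal(prev, founded):
                break
        ok &= ((L == 0) | founded).all(axis=1)
    return L, ok


def is_consistent_bf(graph, profile, notion) -> bool:
    _L, ok = consistent_mask(graph, profile, notion)
    return bool(ok.any())


def enumerate_labelings_bf(graph, profile, notion) -> list[dict[str, NodeLabel]]:
    nodes = list(graph.nodes)
    L, ok = consistent_mask(graph, profile, notion)
    return [
        {node: NodeLabel(int(row[i])) for i, node in enumerate(nodes)}
        for row in L[ok]
    ]


def predict_bf(graph, profile, notion) -> dict[str, PredLabel]:
    nodes = list(graph.nodes)
    L, ok = consistent_mask(graph, profile, notion)
    if not ok.any():
        raise ValueError("inconsistent instance has no predictions")
    sub = L[ok]
    return {
        node: classify(NodeLabel(int(v)) for v in np.unique(sub[:, i]))
        for i, node in enumerate(nodes)
    }


def mcos_bf(
    graph, profile, notion, max_size: int = 4
) -> tuple[int, set[frozenset[tuple[str, Sign]]]]:
    """Minimum correction sets by exhaustive subset search."""
    candidates = [
        (node, sign)
        for node in graph.nodes
        if node not in profile.inputs
        for sign in (Sign.PLUS, Sign.MINUS)
    ]
    for k in range(max_size + 1):
        hits = set()
        for combo in itertools.combinations(candidates, k):
            _L, ok = consistent_mask(graph, profile, notion, repairs=combo)
            if ok.any():
                hits.add(frozenset(combo))
        if hits:
            return k, hits
    raise ValueError(f"no correction set of size <= {max_size}")


def scenfit_bf(graph, profile, notion) -> tuple[int, list[dict[str, NodeLabel]]]:
    """Minimum observation corrections by exhaustive enumeration."""
    nodes = list(graph.nodes)
    idx = {node: i for i, node in enumerate(nodes)}
    L, ok = consistent_mask(graph, profile, notion, check_c1=False)
    cost = np.zeros(len(L), dtype=int)
    for node, obs in profile.discrete.items():
        if node not in idx:
            continue
        allowed = [int(v) for v in allowed_labels(obs)]
        cost += ~np.isin(L[:, idx[node]], allowed)
    cost = np.where(ok, cost, np.iinfo(int).max)
    best = int(cost.min())
    witnesses = [
        {node: NodeLabel(int(row[i])) for i, node in enumerate(nodes)}
        for row in L[cost == best]
    ]
    return best, witnesses
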
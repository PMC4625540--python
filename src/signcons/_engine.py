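"""Branch-and-bound search engine behind consistency, prediction and repair.

The engine works on a compiled integer form of a graph/profile instance and
supports three modes:

``hard``
    all active constraints (C1, C2 and, per notion, C3/C4) are hard; leaves
    are exactly the consistent total labelings.
``mcos``
    C1 is hard (observation domains); C2/C3 violations each cost one repair,
    and at a leaf the foundedness constraint C4 adds one repair per *source*
    strongly connected component of the unfounded justification subgraph.
    The minimum leaf cost equals the minimum-cardinality correction set size
    (argument in docs/methods.md).
``scenfit``
    C2 (and C3/C4 per notion) are hard; each measured node whose label falls
    outside the observation's admitted set costs one correction.

Internally nodes are assigned in breadth-first order from the input nodes
(changes propagate forward, so conflicts surface close to the decision that
caused them) and value order prefers 0 (which never needs justification).
Exhaustive enumerations are sorted afterwards, so callers always see
labelings in lexicographic order over sorted node identifiers with label
order + < 0 < -.
"""

from __future__ import annotations

import itertools
import math
from typing import Callable, Optional

from .discretize import allowed_labels
from .model import (
    ExperimentalProfile,
    InteractionGraph,
    Notion,
    reconcile,
)

LABEL_ORDER = (1, 0, -1)
_LEX_RANK = {1: 0, 0: 1, -1: 2}


class _Stop(Exception):
    """Internal: abort the search (first witness found / limit reached)."""


class CompiledInstance:
    """Integer-indexed view of (graph, profile, notion) for the search."""

    __slots__ = (
        "graph",
        "profile",
        "notion",
        "nodes",
        "pos",
        "n",
        "is_input",
        "preds",
        "succs",
        "obs_allowed",
        "domains",
        "order",
        "slot_of",
        "ready_at",
    )

    def __init__(
        self,
        graph: InteractionGraph,
        profile: ExperimentalProfile,
        notion: Notion,
        *,
        hard_c1: bool = True,
        pinned: Optional[dict] = None,
        forward_order: bool = False,
    ):
        profile = reconcile(graph, profile)
        self.graph = graph
        self.profile = profile
        self.notion = notion
        nodes = list(graph.nodes)
        self.nodes = nodes
        self.n = len(nodes)
        self.pos = {node: i for i, node in enumerate(nodes)}
        self.is_input = [node in profile.inputs for node in nodes]
        self.preds = [
            tuple((self.pos[j], int(s)) for (j, s) in graph.predecessors(node))
            for node in nodes
        ]
        succs: list[list[tuple[int, int]]] = [[] for _ in nodes]
        for i, plist in enumerate(self.preds):
            for (j, s) in plist:
                succs[j].append((i, s))
        self.succs = [tuple(v) for v in succs]

        self.obs_allowed: list[Optional[frozenset[int]]] = []
        domains: list[tuple[int, ...]] = []
        for node in nodes:
            obs = profile.discrete.get(node)
            if obs is None:
                allowed = None
            else:
                allowed = frozenset(int(v) for v in allowed_labels(obs))
            self.obs_allowed.append(allowed)
            if hard_c1 and allowed is not None:
                domains.append(tuple(v for v in LABEL_ORDER if v in allowed))
            else:
                domains.append(LABEL_ORDER)
        if pinned:
            for node, value in pinned.items():
                if node not in self.pos:
                    raise KeyError(f"pinned node {node!r} is not in the graph")
                i = self.pos[node]
                domains[i] = tuple(v for v in domains[i] if v == int(value))
        self.domains = domains

        # assignment order: breadth-first from the inputs and sources along
        # forward edges (keeps every node close to its predecessors so
        # constraint checks fire early), with the ancestor cone of all
        # observation/pin-constrained nodes moved to the front — decisions
        # that can violate a constraint are then taken before the free bulk,
        # so backtracking stays local instead of thrashing
        seeds = sorted(
            i
            for i in range(self.n)
            if self.is_input[i] or not self.preds[i]
        )
        seen = [False] * self.n
        bfs: list[int] = []
        queue = list(seeds)
        for i in queue:
            seen[i] = True
        while queue:
            i = queue.pop(0)
            bfs.append(i)
            for (k, _s) in self.succs[i]:
                if not seen[k]:
                    seen[k] = True
                    queue.append(k)
        for i in range(self.n):
            if not seen[i]:
                bfs.append(i)
        if forward_order:
            # plain breadth-first from the inputs: justifiers precede the
            # nodes they feed, which the founded-prefix sampler requires
            self.order = bfs
        else:
            # constrained cone: backward breadth-first from every node with
            # a restricted domain, goal first — the search then extends a
            # justification chain depth-first towards the inputs, so a
            # failing chain is repaired where it fails, not by distant flips
            cone_rank = {}
            frontier = sorted(i for i in range(self.n) if len(domains[i]) < 3)
            for i in frontier:
                cone_rank[i] = len(cone_rank)
            while frontier:
                nxt: list[int] = []
                for i in frontier:
                    for (j, _s) in self.preds[i]:
                        if j not in cone_rank:
                            cone_rank[j] = len(cone_rank)
                            nxt.append(j)
                frontier = nxt
            self.order = sorted(cone_rank, key=cone_rank.get) + [
                i for i in bfs if i not in cone_rank
            ]

        # slot after which node i and all its predecessors are assigned
        slot_of = [0] * self.n
        for s, i in enumerate(self.order):
            slot_of[i] = s
        self.slot_of = slot_of
        ready: list[list[int]] = [[] for _ in nodes]
        for i in range(self.n):
            s = max([slot_of[i]] + [slot_of[j] for (j, _s) in self.preds[i]])
            ready[s].append(i)
        self.ready_at = [tuple(v) for v in ready]


def _prune_domains(inst: CompiledInstance) -> Optional[list[tuple[int, ...]]]:
    """Remove values that no hard-C2 (and, with C4, input-grounded) support
    can ever justify.  Valid only in modes where C2 is a hard constraint.
    Returns ``None`` when some domain empties (instance infeasible)."""
    doms = [set(d) for d in inst.domains]
    while True:
        changed = False
        # C2: a non-input node can only change if some predecessor supplies
        # a matching influence from its own (current) domain.
        stable = False
        while not stable:
            stable = True
            for i in range(inst.n):
                if inst.is_input[i]:
                    continue
                for v in (1, -1):
                    if v in doms[i] and not any(
                        (v * s) in doms[j] for (j, s) in inst.preds[i]
                    ):
                        doms[i].discard(v)
                        stable = False
                        changed = True
        if inst.notion.uses_c4:
            # least fixpoint of input-grounded support: (i, v) is groundable
            # only if i is an input or some predecessor pair is groundable.
            grounded: set[tuple[int, int]] = set()
            grew = True
            while grew:
                grew = False
                for i in range(inst.n):
                    for v in (1, -1):
                        if v not in doms[i] or (i, v) in grounded:
                            continue
                        if inst.is_input[i] or any(
                            (j, v * s) in grounded for (j, s) in inst.preds[i]
                        ):
                            grounded.add((i, v))
                            grew = True
            for i in range(inst.n):
                if inst.is_input[i]:
                    continue
                keep = {v for v in doms[i] if v == 0 or (i, v) in grounded}
                if keep != doms[i]:
                    doms[i] = keep
                    changed = True
        if not changed:
            break
    if any(not d for d in doms):
        return None
    return [tuple(v for v in LABEL_ORDER if v in d) for d in doms]


def _founded_flags(
    inst: CompiledInstance, labels: list[int], extra_roots: tuple[int, ...] = ()
) -> list[bool]:
    """Foundedness fixpoint: inputs (and extra roots) found the nodes they
    can reach along edges whose influence matches the target's nonzero label."""
    founded = [False] * inst.n
    queue = []
    for i in range(inst.n):
        if inst.is_input[i]:
            founded[i] = True
            queue.append(i)
    for i in extra_roots:
        if not founded[i]:
            founded[i] = True
            queue.append(i)
    while queue:
        j = queue.pop()
        lj = labels[j]
        if lj == 0:
            continue
        for (i, s) in inst.succs[j]:
            if not founded[i] and labels[i] != 0 and lj * s == labels[i]:
                founded[i] = True
                queue.append(i)
    return founded


def _c4_ok(inst: CompiledInstance, labels: list[int]) -> bool:
    founded = _founded_flags(inst, labels)
    return all(labels[i] == 0 or founded[i] for i in range(inst.n))


def _unfounded_scc_sources(
    inst: CompiledInstance, labels: list[int], c2_repaired: tuple[int, ...]
) -> list[tuple[int, ...]]:
    """Source SCCs of the justification subgraph restricted to unfounded
    changed nodes.  Each needs exactly one repair (any of its members)."""
    founded = _founded_flags(inst, labels, extra_roots=c2_repaired)
    unfounded = [i for i in range(inst.n) if labels[i] != 0 and not founded[i]]
    if not unfounded:
        return []
    in_u = set(unfounded)
    adj: dict[int, list[int]] = {i: [] for i in unfounded}
    radj: dict[int, list[int]] = {i: [] for i in unfounded}
    for i in unfounded:
        for (j, s) in inst.preds[i]:
            if j in in_u and labels[j] * s == labels[i]:
                adj[j].append(i)
                radj[i].append(j)

    # iterative Tarjan (recursion-free; justification subgraphs can be deep)
    index_of: dict[int, int] = {}
    low: dict[int, int] = {}
    on_stack: set[int] = set()
    stack: list[int] = []
    sccs: list[tuple[int, ...]] = []
    comp_of: dict[int, int] = {}
    counter = itertools.count()
    for root in unfounded:
        if root in index_of:
            continue
        work = [(root, iter(adj[root]))]
        index_of[root] = low[root] = next(counter)
        stack.append(root)
        on_stack.add(root)
        while work:
            v, it = work[-1]
            advanced = False
            for w in it:
                if w not in index_of:
                    index_of[w] = low[w] = next(counter)
                    stack.append(w)
                    on_stack.add(w)
                    work.append((w, iter(adj[w])))
                    advanced = True
                    break
                elif w in on_stack:
                    low[v] = min(low[v], index_of[w])
            if advanced:
                continue
            work.pop()
            if work:
                pv = work[-1][0]
                low[pv] = min(low[pv], low[v])
            if low[v] == index_of[v]:
                comp = []
                while True:
                    w = stack.pop()
                    on_stack.discard(w)
                    comp_of[w] = len(sccs)
                    comp.append(w)
                    if w == v:
                        break
                sccs.append(tuple(sorted(comp)))
    sources = []
    for ci, comp in enumerate(sccs):
        if all(comp_of[j] == ci for i in comp for j in radj[i]):
            sources.append(comp)
    return sources


#: leaf callback signature: (labels, cost, repair_detail) -> new bound
LeafCallback = Callable[[list[int], int, Optional[tuple]], float]


def dfs(
    inst: CompiledInstance,
    mode: str,
    leaf_cb: LeafCallback,
    *,
    bound: float = math.inf,
    rng=None,
    prune: bool = True,
    founded_prefix: bool = False,
) -> None:
    """Depth-first branch-and-bound; calls ``leaf_cb`` at every admissible
    leaf with cost strictly below the current bound.  The callback returns
    the updated bound (or raises :class:`_Stop` to abort).  ``rng``
    randomizes per-node value order (used for sampling hidden labelings).

    ``founded_prefix`` additionally requires every nonzero node to be
    justified by an *already assigned* founded predecessor.  This is an
    incomplete restriction (foundedness may legitimately arrive through a
    later node), but every leaf it admits is a valid labeling, C4 holds by
    construction, and with the breadth-first assignment order a completion
    always exists — which makes it the right device for *sampling* one
    witness cheaply, not for deciding consistency."""
    if mode not in ("hard", "mcos", "scenfit"):
        raise ValueError(f"unknown search mode {mode!r}")
    use_c3 = inst.notion.uses_c3
    use_c4 = inst.notion.uses_c4
    soft_c2 = mode == "mcos"
    doms: Optional[list[tuple[int, ...]]] = list(inst.domains)
    if prune and not soft_c2:
        doms = _prune_domains(inst)
        if doms is None:
            return
    if rng is not None:
        doms = [tuple(int(v) for v in rng.permutation(list(d))) for d in doms]
    elif founded_prefix:
        # change-first: justification chains then grow greedily from the
        # inputs, which is what makes the founded-prefix pass find a witness
        # quickly instead of discovering missing chains by backtracking
        doms = [tuple(sorted(d, key=lambda v: (v == 0, _LEX_RANK[v]))) for d in doms]
    else:
        # prefer 0: it needs no justification and founds nothing wrongly
        doms = [
            tuple(sorted(d, key=lambda v: (v != 0, _LEX_RANK[v]))) for d in doms
        ]
    # a nonzero value with no conceivable justifier always costs one repair;
    # charging it at assignment time tightens the bound early (mcos only)
    hopeless = [
        {
            v: (
                not inst.is_input[i]
                and v != 0
                and not any((v * s) in doms[j] for (j, s) in inst.preds[i])
            )
            for v in doms[i]
        }
        for i in range(inst.n)
    ]
    n = inst.n
    labels = [0] * n
    assigned = [False] * n
    preds = inst.preds
    succs = inst.succs
    is_input = inst.is_input
    ready_at = inst.ready_at
    order = inst.order
    obs_allowed = inst.obs_allowed
    domsets = [frozenset(d) for d in doms]
    founded = [False] * n
    state = [bound]

    def check_ready(i: int) -> Optional[tuple]:
        """C2/C3 status of node i once it and its predecessors are labeled."""
        v = labels[i]
        if is_input[i]:
            return None
        if v != 0:
            if soft_c2 and hopeless[i][v]:
                return None  # already charged at assignment time
            for (j, s) in preds[i]:
                if labels[j] * s == v:
                    return None
            return ("C2", i)
        if use_c3:
            pos = neg = False
            for (j, s) in preds[i]:
                w = labels[j] * s
                if w > 0:
                    pos = True
                elif w < 0:
                    neg = True
            if (pos or neg) and not (pos and neg):
                return ("C3", i, -1 if pos else 1)
        return None

    def viable(i: int) -> bool:
        """Can node i's assigned value still satisfy C2/C3, given assigned
        predecessors and the static domains of unassigned ones?  Exact once
        all predecessors are assigned; sound (never prunes a satisfiable
        branch) before that.  Hard-constraint modes only."""
        v = labels[i]
        if is_input[i]:
            return True
        if v != 0:
            maybe = False
            for (j, s) in preds[i]:
                if assigned[j]:
                    if labels[j] * s == v:
                        return True
                elif (v * s) in domsets[j]:
                    maybe = True
            return maybe
        if not use_c3:
            return True
        has_pos = has_neg = False  # assigned influences
        can_pos = can_neg = False  # any edge that can (still) supply the sign
        forced_pos = forced_neg = False  # unassigned pred certain to supply it
        for (j, s) in preds[i]:
            if assigned[j]:
                w = labels[j] * s
                if w > 0:
                    has_pos = can_pos = True
                elif w < 0:
                    has_neg = can_neg = True
            else:
                dj = domsets[j]
                if s in dj:
                    can_pos = True
                if -s in dj:
                    can_neg = True
                if 0 not in dj:
                    if dj == frozenset({s}):
                        forced_pos = True
                    elif dj == frozenset({-s}):
                        forced_neg = True
        if (has_pos or forced_pos) and not can_neg:
            return False
        if (has_neg or forced_neg) and not can_pos:
            return False
        return True

    def c4_viable() -> bool:
        """Optimistic foundedness over the assigned prefix: an assigned
        changed node is foundable if it has an unassigned predecessor whose
        domain can still justify it, or an assigned justifying predecessor
        that is itself foundable.  Sound at any prefix and exact at a leaf
        (no unassigned predecessors left)."""
        opt = [False] * n
        queue = []
        for i in range(n):
            if is_input[i]:
                opt[i] = True
                queue.append(i)
            elif assigned[i] and labels[i] != 0:
                v = labels[i]
                for (j, s) in preds[i]:
                    if not assigned[j] and (v * s) in domsets[j]:
                        opt[i] = True
                        queue.append(i)
                        break
        while queue:
            j = queue.pop()
            if not assigned[j] or labels[j] == 0:
                # an unassigned foundable predecessor already counts through
                # the root rule; it cannot transmit through a known label
                continue
            for (i, s) in succs[j]:
                if (
                    not opt[i]
                    and assigned[i]
                    and labels[i] != 0
                    and labels[j] * s == labels[i]
                ):
                    opt[i] = True
                    queue.append(i)
        return all(opt[i] or not assigned[i] or labels[i] == 0 for i in range(n))

    def leaf(cost: int, c2: tuple[int, ...], c3: tuple[tuple[int, int], ...]):
        if use_c4:
            if mode == "mcos":
                sources = _unfounded_scc_sources(inst, labels, c2)
                cost += len(sources)
                if cost >= state[0]:
                    return
                state[0] = leaf_cb(labels, cost, (c2, c3, tuple(sources)))
                return
            if not _c4_ok(inst, labels):
                return
        if mode == "mcos":
            state[0] = leaf_cb(labels, cost, (c2, c3, ()))
        else:
            state[0] = leaf_cb(labels, cost, None)

    def recurse(slot: int, cost: int, c2: tuple, c3: tuple):
        if slot == n:
            leaf(cost, c2, c3)
            return
        p = order[slot]
        assigned[p] = True
        for v in doms[p]:
            labels[p] = v
            if founded_prefix:
                if is_input[p]:
                    founded[p] = True
                elif v != 0:
                    founded[p] = any(
                        assigned[j] and j != p and founded[j]
                        and labels[j] * s == v
                        for (j, s) in preds[p]
                    )
                    if not founded[p]:
                        continue
                else:
                    founded[p] = False
            ncost = cost
            nc2 = c2
            nc3 = c3
            if mode == "scenfit":
                a = obs_allowed[p]
                if a is not None and v not in a:
                    ncost += 1
            elif soft_c2 and hopeless[p][v]:
                ncost += 1
                nc2 = nc2 + (p,)
            feasible = ncost < state[0]
            if feasible and soft_c2:
                # repairs make every violation payable: charge exact C2/C3
                # verdicts once a node and its predecessors are all labeled
                for i in ready_at[slot]:
                    res = check_ready(i)
                    if res is None:
                        continue
                    ncost += 1
                    if res[0] == "C2":
                        nc2 = nc2 + (i,)
                    else:
                        nc3 = nc3 + ((res[1], res[2]),)
                    if ncost >= state[0]:
                        feasible = False
                        break
            elif feasible:
                # hard constraints: prune the moment a value becomes dead,
                # both for this node and for assigned successors it feeds
                if not viable(p):
                    feasible = False
                else:
                    for (k, _s) in succs[p]:
                        if assigned[k] and k != p and not viable(k):
                            feasible = False
                            break
                if (
                    feasible
                    and use_c4
                    and not founded_prefix
                    and not c4_viable()
                ):
                    feasible = False
            if feasible:
                recurse(slot + 1, ncost, nc2, nc3)
        assigned[p] = False

    try:
        recurse(0, 0, (), ())
    except _Stop:
        pass


def find_one(
    inst: CompiledInstance,
    mode: str = "hard",
    *,
    bound: float = math.inf,
    rng=None,
    founded_prefix: bool = False,
) -> Optional[tuple[list[int], int]]:
    """First admissible leaf with cost < bound, or ``None``."""
    result: list = []

    def cb(labels, cost, _detail):
        result.append((list(labels), cost))
        raise _Stop

    dfs(inst, mode, cb, bound=bound, rng=rng, founded_prefix=founded_prefix)
    return result[0] if result else None


def minimize(
    inst: CompiledInstance, mode: str, *, max_cost: int, min_cost: int = 0
) -> Optional[int]:
    """Minimum leaf cost by iterative deepening, or ``None`` if it exceeds
    ``max_cost``.  Each level k proves 'no leaf costs < k' before moving on,
    so the first hit is optimal (``min_cost`` skips levels already proven
    infeasible, e.g. cost 0 once inconsistency is established)."""
    for k in range(min_cost, max_cost + 1):
        hit = find_one(inst, mode, bound=k + 1)
        if hit is not None:
            return hit[1]
    return None


def enumerate_leaves(
    inst: CompiledInstance,
    mode: str,
    *,
    cost_target: int,
    limit: Optional[int] = None,
) -> list[tuple[list[int], int, Optional[tuple]]]:
    """All admissible leaves of cost exactly ``cost_target``, sorted
    lexicographically (label order + < 0 < - over sorted node ids)."""
    from .model import LimitExceededError

    out: list = []

    def cb(labels, cost, detail):
        if cost == cost_target:
            out.append((list(labels), cost, detail))
            if limit is not None and len(out) > limit:
                raise _Stop
        return cost_target + 1  # keep exploring everything at the target cost

    dfs(inst, mode, cb, bound=cost_target + 1)
    if limit is not None and len(out) > limit:
        raise LimitExceededError(
            f"more than {limit} labelings at cost {cost_target}; raise the limit"
        )
    out.sort(key=lambda rec: tuple(_LEX_RANK[v] for v in rec[0]))
    return out
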
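"""Discretization of real-valued measurements into the five-valued alphabet.

Log-ratio measurements are mapped through four condition-dependent thresholds
t1 <= t2 < 0 < t3 <= t4 into certain calls (-, 0, +) and uncertain bands
(u-, u+).  An uncertain observation restricts the node's label to two of the
three values {+, 0, -} instead of pinning it to one.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping

from .model import (
    DEFAULT_THRESHOLDS,
    DiscretizationThresholds,
    ExperimentalProfile,
    NodeLabel,
    ObsLabel,
)

__all__ = ["discretize_value", "discretize_profile", "allowed_labels"]


def discretize_value(
    x: float, thresholds: DiscretizationThresholds = DEFAULT_THRESHOLDS
) -> ObsLabel:
    """Map one measurement to an observation label.

    Piecewise:  x <= t1 -> '-';  t1 < x <= t2 -> 'u-';  t2 < x < t3 -> '0';
    t3 <= x < t4 -> 'u+';  t4 <= x -> '+'.  The five preimage intervals
    partition the reals, so the mapping is total and monotone under the
    order  - < u- < 0 < u+ < +.
    """
    if not math.isfinite(x):
        raise ValueError(f"cannot discretize non-finite value {x!r}")
    th = thresholds
    if x <= th.t1:
        return ObsLabel.DOWN
    if x <= th.t2:
        return ObsLabel.UNCERTAIN_DOWN
    if x < th.t3:
        return ObsLabel.ZERO
    if x < th.t4:
        return ObsLabel.UNCERTAIN_UP
    return ObsLabel.UP


def discretize_profile(
    raw: Mapping[str, float],
    inputs: Iterable[str] = (),
    thresholds: DiscretizationThresholds = DEFAULT_THRESHOLDS,
) -> ExperimentalProfile:
    """Build an experimental profile from raw measurements.

    Every raw value is discretized through ``thresholds``; the measured set is
    the domain of ``raw``.  An empty profile is rejected.
    """
    if not raw:
        raise ValueError("empty measurement mapping; a profile needs observations")
    discrete = {}
    for node, value in raw.items():
        try:
            discrete[node] = discretize_value(value, thresholds)
        except ValueError as exc:
            raise ValueError(f"node {node!r}: {exc}") from exc
    return ExperimentalProfile(discrete=discrete, inputs=frozenset(inputs), raw=raw)


_ALLOWED = {
    ObsLabel.UP: frozenset({NodeLabel.UP}),
    ObsLabel.UNCERTAIN_UP: frozenset({NodeLabel.UP, NodeLabel.ZERO}),
    ObsLabel.ZERO: frozenset({NodeLabel.ZERO}),
    ObsLabel.UNCERTAIN_DOWN: frozenset({NodeLabel.DOWN, NodeLabel.ZERO}),
    ObsLabel.DOWN: frozenset({NodeLabel.DOWN}),
}


def allowed_labels(obs: ObsLabel) -> frozenset[NodeLabel]:
    """Node labels admitted by an observation (Constraint 1 per node).

    Certain observations fix the label; uncertain ones admit two values:
    u+ -> {+, 0} and u- -> {-, 0}.
    """
    return _ALLOWED[ObsLabel(obs)]
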
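"""Plain-text formats and machine-readable reports.

Networks are strict tab-separated edge lists ``source<TAB>sign<TAB>target``
with sign ``+``, ``-`` or ``?`` (unsigned: expanded into two parallel edges
of opposite sign); a two-field line ``node<TAB><id>`` declares an isolated
node.  Observation files are ``node<TAB>value`` lines where the value is a
real number (discretized through the thresholds), a token among
``+ - 0 u+ u-`` (taken as the observation directly), or the word ``input``
marking a perturbed node.  ``#``-prefixed and blank lines are ignored.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .discretize import discretize_value
from .model import (
    DEFAULT_THRESHOLDS,
    DiscretizationThresholds,
    ExperimentalProfile,
    InteractionGraph,
    NodeLabel,
    Notion,
    ObsLabel,
    ParseError,
    Sign,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_network",
    "write_network",
    "read_observations",
    "write_observations",
    "write_labeling",
    "read_labeling",
    "write_report",
    "predictions_tsv",
]

REPORT_SCHEMA = 1
_OBS_TOKENS = {o.token for o in ObsLabel}


@dataclass(frozen=True)
class RunConfig:
    """Shared run settings for the command-line interface."""

    notion: Notion = Notion.FSP
    thresholds: DiscretizationThresholds = DEFAULT_THRESHOLDS
    auto_inputs: bool = True
    limit_labelings: int = 10**6
    max_repairs: int = 32
    seed: int = 0
    json_path: Optional[Path] = None
    tsv_path: Optional[Path] = None

    def __post_init__(self):
        if self.limit_labelings <= 0 or self.max_repairs <= 0:
            raise ValueError("caps must be positive")


def _content_lines(path) -> list[tuple[int, str]]:
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            out.append((no, line))
    return out


def read_network(path) -> InteractionGraph:
    """Parse a tab-separated signed edge list."""
    edges = []
    extra_nodes = []
    for no, line in _content_lines(path):
        parts = line.split("\t")
        if len(parts) == 2 and parts[0] == "node":
            extra_nodes.append(parts[1])
            continue
        if len(parts) != 3:
            raise ParseError(
                f"{path}:{no}: expected 'source<TAB>sign<TAB>target', got {line!r}"
            )
        src, sign_token, tgt = parts
        if sign_token == "?":
            edges.append((src, tgt, Sign.PLUS))
            edges.append((src, tgt, Sign.MINUS))
        elif sign_token in ("+", "-"):
            edges.append((src, tgt, Sign.from_token(sign_token)))
        else:
            raise ParseError(
                f"{path}:{no}: unknown sign token {sign_token!r} (expected +, - or ?)"
            )
    try:
        graph = InteractionGraph(edges, nodes=extra_nodes)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    logger.info(
        "read network %s: %d nodes, %d edges", path, len(graph), len(graph.edges)
    )
    return graph


def write_network(graph: InteractionGraph, path) -> None:
    """Write the exact edge list back (one signed edge per line)."""
    with open(path, "w", encoding="utf-8") as fh:
        for (src, tgt, sign) in graph.edges:
            fh.write(f"{src}\t{sign.token}\t{tgt}\n")
        covered = {e.source for e in graph.edges} | {e.target for e in graph.edges}
        for node in graph.nodes:
            if node not in covered:
                fh.write(f"node\t{node}\n")


def read_observations(
    path,
    thresholds: DiscretizationThresholds = DEFAULT_THRESHOLDS,
    token_mode: Optional[bool] = None,
) -> ExperimentalProfile:
    """Parse an observation table.

    ``token_mode`` forces the value dialect: ``True`` requires discrete
    tokens, ``False`` requires numeric values, ``None`` auto-detects per
    line.  A node may carry at most one observation line plus at most one
    ``input`` line.  Raw values are kept only when every observation in the
    file is numeric (so the raw and discrete domains stay aligned).
    """
    discrete: dict[str, ObsLabel] = {}
    raw: dict[str, float] = {}
    inputs: set[str] = set()
    any_token = False
    for no, line in _content_lines(path):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(
                f"{path}:{no}: expected 'node<TAB>value', got {line!r}"
            )
        node, value = parts
        if value == "input":
            if node in inputs:
                raise ParseError(f"{path}:{no}: duplicate input line for {node!r}")
            inputs.add(node)
            continue
        if node in discrete:
            raise ParseError(f"{path}:{no}: duplicate observation for {node!r}")
        if value in _OBS_TOKENS:
            if token_mode is False:
                raise ParseError(
                    f"{path}:{no}: token value {value!r} in numeric mode"
                )
            discrete[node] = ObsLabel.from_token(value)
            any_token = True
            continue
        if token_mode is True:
            raise ParseError(
                f"{path}:{no}: expected a token among + - 0 u+ u- or 'input', "
                f"got {value!r}"
            )
        try:
            x = float(value)
        except ValueError:
            raise ParseError(
                f"{path}:{no}: value {value!r} is neither a number, a token "
                "among + - 0 u+ u-, nor 'input'"
            )
        try:
            discrete[node] = discretize_value(x, thresholds)
        except ValueError as exc:
            raise ParseError(f"{path}:{no}: {exc}") from exc
        raw[node] = x
    profile = ExperimentalProfile(
        discrete=discrete,
        inputs=inputs,
        raw=raw if (raw and not any_token) else None,
    )
    logger.info(
        "read observations %s: %d measured, %d inputs",
        path,
        len(discrete),
        len(inputs),
    )
    return profile


def write_observations(profile: ExperimentalProfile, path) -> None:
    """Write a profile as a token observation table (round-trippable)."""
    with open(path, "w", encoding="utf-8") as fh:
        for node in sorted(profile.discrete):
            fh.write(f"{node}\t{profile.discrete[node].token}\n")
        for node in sorted(profile.inputs):
            fh.write(f"{node}\tinput\n")


def write_labeling(labeling: dict[str, NodeLabel], path) -> None:
    """Write a node -> label table (e.g. a synthetic ground truth)."""
    with open(path, "w", encoding="utf-8") as fh:
        for node in sorted(labeling):
            fh.write(f"{node}\t{NodeLabel(labeling[node]).token}\n")


def read_labeling(path) -> dict[str, NodeLabel]:
    out: dict[str, NodeLabel] = {}
    for no, line in _content_lines(path):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}:{no}: expected 'node<TAB>label'")
        try:
            out[parts[0]] = NodeLabel.from_token(parts[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{no}: {exc}") from exc
    return out


def predictions_tsv(predictions) -> str:
    """Prediction map as 'node<TAB>token' lines sorted by node id."""
    return "".join(
        f"{node}\t{predictions[node].token}\n" for node in sorted(predictions)
    )


def write_report(
    results: dict,
    path_json: Optional[Path] = None,
    path_tsv: Optional[Path] = None,
) -> str:
    """Serialize a result dictionary as versioned JSON (byte-stable for
    fixed inputs and seed) and, when predictions are present, as a TSV
    table.  Returns the JSON text."""
    payload = {"schema": REPORT_SCHEMA, **results}
    text = json.dumps(payload, indent=2, sort_keys=True) + "\n"
    if path_json is not None:
        Path(path_json).write_text(text, encoding="utf-8")
    if path_tsv is not None and "predictions" in results:
        preds = results["predictions"]
        lines = "".join(f"{n}\t{t}\n" for n, t in sorted(preds.items()))
        Path(path_tsv).write_text(lines, encoding="utf-8")
    return text
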
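"""Evaluation metrics: recovery, information gain, precision, confusion
matrices, cross-validation and shuffle-null procedures.

Recovery is the fraction of unmeasured nodes receiving any prediction.
Information gain measures, on a log scale, how much the predictions shrink
the space of admissible behavior combinations: n unconstrained nodes admit
3^n combinations; k strong predictions pin their nodes, l weak predictions
leave 2 values each and m unpredicted nodes leave 3, giving

    gain = (n*log 3 - l*log 2 - m*log 3) / (n*log 3).

Precision is TP/(TP+FP) where a prediction is validated only against a
*certain* held-out observation: strong predictions must match exactly, w+
accepts + or 0, w- accepts - or 0, chg accepts + or -; any other certain
observation is a false positive, and uncertain observations are not counted
(they do appear as confusion-matrix rows).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections.abc import Iterable, Mapping, Sequence
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    ExperimentalProfile,
    InteractionGraph,
    NodeLabel,
    Notion,
    ObsLabel,
)
from .predict import PredLabel, PredictionMap
from .repair import inconsistency_index, predict_under_mcos

__all__ = [
    "PredictionCounts",
    "EvalReport",
    "NullResult",
    "recovery_rate",
    "information_gain",
    "validate_prediction",
    "precision",
    "confusion_matrix",
    "crossval",
    "null_distribution",
    "paired_null_test",
]


@dataclass(frozen=True)
class PredictionCounts:
    """Counts over unmeasured nodes: strong (k), weak (l), none (m)."""

    n: int
    k: int
    l: int
    m: int

    def __post_init__(self):
        if min(self.n, self.k, self.l, self.m) < 0:
            raise ValueError("counts must be non-negative")
        if self.k + self.l + self.m != self.n:
            raise ValueError(
                f"k + l + m must equal n ({self.k}+{self.l}+{self.m} != {self.n})"
            )

    @classmethod
    def from_predictions(
        cls, pm: PredictionMap, nodes: Iterable[str]
    ) -> "PredictionCounts":
        k = l = m = n = 0
        for node in nodes:
            n += 1
            p = pm[node]
            if p.is_strong:
                k += 1
            elif p.is_weak:
                l += 1
            else:
                m += 1
        return cls(n=n, k=k, l=l, m=m)


def recovery_rate(pm: PredictionMap, unmeasured: Iterable[str]) -> float:
    """Fraction of unmeasured nodes with a prediction other than 'no'."""
    nodes = list(unmeasured)
    if not nodes:
        raise ValueError("recovery rate undefined over an empty node set")
    predicted = sum(1 for x in nodes if pm[x] is not PredLabel.NO)
    return predicted / len(nodes)


def information_gain(counts: PredictionCounts) -> float:
    """Log-scale reduction of admissible behavior combinations, in [0, 1].

    Equals 1 when every node is strongly predicted and 0 when none is.
    Linear in (k, l, m), so gains of strong and weak predictions add.
    """
    if counts.n == 0:
        raise ValueError("information gain undefined for n = 0")
    log2, log3 = math.log(2.0), math.log(3.0)
    return (counts.n * log3 - counts.l * log2 - counts.m * log3) / (counts.n * log3)


_WEAK_ACCEPTS = {
    PredLabel.WEAK_UP: (NodeLabel.UP, NodeLabel.ZERO),
    PredLabel.WEAK_DOWN: (NodeLabel.DOWN, NodeLabel.ZERO),
    PredLabel.CHANGE: (NodeLabel.UP, NodeLabel.DOWN),
}

_STRONG_VALUE = {
    PredLabel.UP: NodeLabel.UP,
    PredLabel.DOWN: NodeLabel.DOWN,
    PredLabel.ZERO: NodeLabel.ZERO,
}


def validate_prediction(pred: PredLabel, obs: ObsLabel) -> str:
    """'TP', 'FP', or 'uncounted' (uncertain observation)."""
    if pred is PredLabel.NO:
        raise ValueError("'no' is not a prediction and cannot be validated")
    value = obs.certain_label
    if value is None:
        return "uncounted"
    if pred in _STRONG_VALUE:
        return "TP" if value is _STRONG_VALUE[pred] else "FP"
    return "TP" if value in _WEAK_ACCEPTS[pred] else "FP"


def precision(
    pm: PredictionMap, validation: Mapping[str, ObsLabel]
) -> tuple[float, dict[PredLabel, float]]:
    """Overall and per-class TP/(TP+FP) against certain validation data."""
    tp: dict[PredLabel, int] = {}
    fp: dict[PredLabel, int] = {}
    counted = 0
    for node, obs in validation.items():
        pred = pm.get(node)
        if pred is None or pred is PredLabel.NO:
            continue
        verdict = validate_prediction(pred, obs)
        if verdict == "uncounted":
            continue
        counted += 1
        (tp if verdict == "TP" else fp)[pred] = (
            (tp if verdict == "TP" else fp).get(pred, 0) + 1
        )
    if counted == 0:
        raise ValueError("no prediction/certain-observation pair to validate")
    total_tp = sum(tp.values())
    by_class = {}
    for cls in set(tp) | set(fp):
        t, f = tp.get(cls, 0), fp.get(cls, 0)
        by_class[cls] = t / (t + f)
    return total_tp / counted, by_class


PRED_COLUMNS = [p.token for p in PredLabel]
OBS_ROWS = [o.token for o in ObsLabel]


def confusion_matrix(
    pm: PredictionMap, validation: Mapping[str, ObsLabel]
) -> pd.DataFrame:
    """Cross-tabulation: rows = measured behavior, columns = prediction.

    Includes rows for uncertain observations and a 'no' column; the cell sum
    equals the number of validated nodes (those with both a prediction-map
    entry and a validation observation).
    """
    mat = pd.DataFrame(0, index=OBS_ROWS, columns=PRED_COLUMNS, dtype=int)
    for node, obs in validation.items():
        pred = pm.get(node)
        if pred is None:
            continue
        mat.loc[obs.token, pred.token] += 1
    return mat


@dataclass
class EvalReport:
    """Aggregated cross-validation outcome (unweighted means over samples)."""

    notion: Notion
    fraction: float
    n_samples: int
    recovery: float
    info_gain: float
    precision_overall: Optional[float]
    precision_by_class: dict[PredLabel, float]
    confusion: pd.DataFrame  # mean counts per sample
    samples: pd.DataFrame  # one row per sample
    no_validation: bool = False

    def to_json_dict(self) -> dict:
        return {
            "notion": self.notion.value,
            "fraction": self.fraction,
            "n_samples": self.n_samples,
            "recovery": self.recovery,
            "info_gain": self.info_gain,
            "precision_overall": self.precision_overall,
            "precision_by_class": {
                k.token: v for k, v in sorted(self.precision_by_class.items(),
                                              key=lambda kv: kv[0].token)
            },
            "confusion": {
                row: {col: int(round(v * self.n_samples))
                      for col, v in cols.items()}
                for row, cols in self.confusion.to_dict(orient="index").items()
            },
            "no_validation": self.no_validation,
        }

    def to_tsv(self) -> str:
        """Per-sample table plus one summary row, tab-separated."""
        df = self.samples.copy()
        summary = {
            "sample": "mean",
            "recovery": self.recovery,
            "info_gain": self.info_gain,
            "precision": self.precision_overall,
        }
        df = pd.concat([df, pd.DataFrame([summary])], ignore_index=True)
        return df.to_csv(sep="\t", index=False)


def _sample_rng(seed: int, k: int) -> np.random.Generator:
    return np.random.default_rng([seed, k])


def crossval(
    graph: InteractionGraph,
    profile: ExperimentalProfile,
    fraction: float,
    n_samples: int,
    notion: Notion = Notion.FSP,
    seed: int = 0,
) -> EvalReport:
    """Cross-validation by repeated subsampling of the measurements.

    Each sample keeps a random ``fraction`` share of the observations
    (inputs unchanged), computes predictions under all minimum correction
    sets, and validates them against the held-out observations.  Recovery
    and information gain are computed over the nodes unmeasured in the
    sample; aggregation is an unweighted mean over samples.  Fully
    deterministic for a fixed seed.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    measured = sorted(profile.measured & set(graph.nodes))
    if len(measured) < 2:
        raise ValueError("cross-validation needs at least 2 measurements")
    n_keep = math.ceil(fraction * len(measured))
    rows = []
    confusions = []
    precisions_by_class: dict[PredLabel, list[float]] = {}
    no_validation = n_keep == len(measured)
    for k in range(n_samples):
        rng = _sample_rng(seed, k)
        keep = sorted(rng.choice(measured, size=n_keep, replace=False))
        reduced = profile.subset(keep)
        pm = predict_under_mcos(graph, reduced, notion)
        unmeasured = [n for n in graph.nodes if n not in reduced.measured]
        counts = PredictionCounts.from_predictions(pm, unmeasured)
        rec = recovery_rate(pm, unmeasured)
        gain = information_gain(counts)
        held_out = {n: profile.discrete[n] for n in measured if n not in set(keep)}
        prec: Optional[float] = None
        if held_out:
            confusions.append(confusion_matrix(pm, held_out))
            try:
                prec, by_class = precision(pm, held_out)
                for cls, v in by_class.items():
                    precisions_by_class.setdefault(cls, []).append(v)
            except ValueError:
                prec = None  # nothing countable in this sample
        rows.append(
            {"sample": k, "recovery": rec, "info_gain": gain, "precision": prec}
        )
    samples = pd.DataFrame(rows)
    prec_values = samples["precision"].dropna()
    confusion = (
        sum(confusions) / len(confusions)
        if confusions
        else pd.DataFrame(0.0, index=OBS_ROWS, columns=PRED_COLUMNS)
    )
    return EvalReport(
        notion=notion,
        fraction=fraction,
        n_samples=n_samples,
        recovery=float(samples["recovery"].mean()),
        info_gain=float(samples["info_gain"].mean()),
        precision_overall=(
            float(prec_values.mean()) if len(prec_values) else None
        ),
        precision_by_class={
            cls: float(np.mean(v)) for cls, v in precisions_by_class.items()
        },
        confusion=confusion,
        samples=samples,
        no_validation=no_validation,
    )


@dataclass(frozen=True)
class NullResult:
    """Shuffle-null comparison for one experimental profile."""

    real_index: float
    shuffled_indices: tuple[float, ...]
    p_value: float  # empirical quantile of the real index in the null
    degenerate: bool  # all observations identical: the null collapses


def null_distribution(
    graph: InteractionGraph,
    profile: ExperimentalProfile,
    n_shuffles: int,
    notion: Notion = Notion.FSP,
    seed: int = 0,
) -> NullResult:
    """Inconsistency index of the real profile against a sign-shuffled null.

    Shuffling permutes the observed labels among the measured nodes, which
    preserves the sign distribution exactly.  The single-profile p-value is
    the empirical quantile (1 + #{null <= real}) / (1 + n_shuffles): small
    values mean the real data are more sign-consistent with the topology
    than random relabelings.  For a collection of profiles, compare
    per-profile real and mean-null indices with :func:`paired_null_test`.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    measured = sorted(profile.measured & set(graph.nodes))
    labels = [profile.discrete[n] for n in measured]
    degenerate = len(set(labels)) <= 1
    real = inconsistency_index(graph, profile, notion)
    shuffled = []
    for k in range(n_shuffles):
        rng = _sample_rng(seed, k)
        perm = rng.permutation(len(measured))
        discrete = dict(profile.discrete)
        for node, j in zip(measured, perm):
            discrete[node] = labels[j]
        null_profile = ExperimentalProfile(discrete=discrete, inputs=profile.inputs)
        shuffled.append(inconsistency_index(graph, null_profile, notion))
    n_le = sum(1 for v in shuffled if v <= real)
    p_value = (1 + n_le) / (1 + n_shuffles)
    return NullResult(
        real_index=real,
        shuffled_indices=tuple(shuffled),
        p_value=p_value,
        degenerate=degenerate,
    )


def paired_null_test(
    real_indices: Sequence[float], null_indices: Sequence[float]
) -> float:
    """Wilcoxon signed-rank p-value comparing per-experiment real indices
    with their mean shuffled-null indices (standard paired rank test)."""
    if len(real_indices) != len(null_indices):
        raise ValueError("paired test needs equal-length sequences")
    stat = stats.wilcoxon(np.asarray(real_indices), np.asarray(null_indices))
    return float(stat.pvalue)
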
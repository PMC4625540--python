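# signcons

Sign-consistency analysis of interaction graphs against steady-state-shift
experimental profiles: consistency checking, cautious prediction, and repair.

## The problem

Signaling and gene-regulatory knowledge is commonly summarized as an
*interaction graph* (IG): a signed directed graph (V, E, σ) where an edge
j → i with sign + (−) means j tends to increase (decrease) i. A
steady-state shift experiment (perturb the system, let it settle, measure
log-ratios of node levels) yields a partial, discretized picture of how the
system moved: each measured species is called up (+), down (−), unchanged
(0), or lands in one of two uncertain bands (u+, u−) defined by four
thresholds t₁ ≤ t₂ < 0 < t₃ ≤ t₄.

`signcons` confronts the two. A candidate system behavior is a *total
labeling* μᵗ: V → {+, 0, −}; it is admissible when it satisfies, per node:

- **C1** — the labeling agrees with the (possibly uncertain) observation:
  a `u+` call admits {+, 0}, a `u−` call admits {−, 0}, certain calls pin
  the label;
- **C2** — a change at a non-input node is justified by a predecessor:
  some edge j → i has μᵗ(j)·σ(j,i) = μᵗ(i);
- **C3** — a 0-change at a non-input node is justified: the node receives
  no nonzero influence, or two opposing ones;
- **C4** — a change is *founded*: reachable from a perturbed input along a
  chain of sign-matching influences, which excludes self-sustaining
  explanations through positive feedback loops.

Four global notions combine these constraints — WP (C1–C2), SP (+C3),
FWP (C1, C2, C4), FSP (all four) — and become strictly more selective in
that order. On top of the admissible-labeling sets the package computes:

- **Consistency** — does any admissible labeling exist?
- **Cautious predictions** — strong (+/−/0: same label in every admissible
  labeling) and weak (⊕ `w+`, ⊖ `w-`, ± `chg`: one of the three behaviors
  excluded everywhere);
- **Minimum correction sets (MCoS)** — smallest sets of artificial signed
  input influences restoring consistency; their size over the observation
  count is the *inconsistency index*, and predictions under all minimal
  repairs remain available for inconsistent instances;
- **SCEN-FIT** — the minimum number of observation corrections over all
  propagation-satisfying labelings;
- **Evaluation** — recovery rate, information gain
  (n·log3 − l·log2 − m·log3)/(n·log3) for k strong / l weak / m unpredicted
  nodes, precision against held-out certain observations, confusion
  matrices, subsampling cross-validation, and a sign-shuffle null for the
  inconsistency index.

It is aimed at systems biologists who want to (in)validate a curated
network against expression profiles, predict unmeasured responses, or
locate the influences a model is missing.

## Worked example

A regulator C feeds both A and B positively, yet A is measured strongly up
(log-ratio 2.5) and B strongly down (−2.1):

```sh
printf 'C\t+\tA\nC\t+\tB\n' > network.tsv
printf 'A\t2.5\nB\t-2.1\nC\tinput\n' > observations.tsv
signcons mcos --network network.tsv --obs observations.tsv --notion FSP
```

```json
{
  "consistent": false,
  "inconsistency_index": 0.5,
  "mcos_sets": [["A:+"], ["B:-"]],
  "mcos_size": 1,
  "notion": "FSP",
  "predictions": {"A": "+", "B": "-", "C": "chg"},
  "schema": 1,
  "seed": 0,
  "versions": {"signcons": "0.1.0"}
}
```

No labeling of C explains both observations, so the instance is
inconsistent. One added influence suffices (`mcos_size: 1`), in exactly two
ways: a positive artificial influence on A (then C = −) or a negative one
on B (then C = +). The index 0.5 is that one repair over two observations.
Because C changes direction under *every* minimal repair, it is cautiously
predicted `chg` (±) — an unmeasured regulator predicted to move without
knowing which way.

The same operations are available as library calls
(`signcons.mcos(graph, profile, Notion.FSP)` …), and
`signcons synth` generates networks and profiles with a known hidden
consistent labeling for testing pipelines end to end. Other subcommands:
`check`, `predict`, `scenfit`, `crossval`, `null`.

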
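# Methods

## Model

An interaction graph (V, E, σ) is a signed directed multigraph: parallel
edges with opposite signs are kept (they encode unsigned interactions),
exact duplicates collapse, self-loops are allowed. An experimental profile
(S, I, μ) carries the measured set S with five-valued observations μ and
the input set I of perturbed (or predecessor-free) nodes. Inputs need not
be measured: in genome-scale stress experiments the true perturbation
targets are unknown and one designates all predecessor-free nodes as
inputs; an unmeasured input has a free label. Observations naming species
outside the network are dropped at reconciliation with a logged count —
profiles routinely cover more genes than any curated model.

Discretization maps a log-ratio x through thresholds t₁ ≤ t₂ < 0 < t₃ ≤ t₄
(defaults −2, −0.01, 0.01, 2, overridable per run since they are
condition-dependent): x ≤ t₁ → −, t₁ < x ≤ t₂ → u−, t₂ < x < t₃ → 0,
t₃ ≤ x < t₄ → u+, t₄ ≤ x → +. Degenerate thresholds (t₁ = t₂ or t₃ = t₄)
are legal and empty the uncertain band. The five preimages partition the
reals and the map is monotone.

## Constraints and notions

For a total labeling μᵗ: V → {+, 0, −}:

- **C1 (observations)**: μᵗ(i) must lie in the set admitted by μ(i); the
  uncertain calls admit two labels ({+,0} and {−,0}).
- **C2 (changes justified)**: a non-input i with μᵗ(i) ≠ 0 needs an edge
  j → i with μᵗ(j)·σ(j,i) = μᵗ(i). 0-changes are unconstrained here —
  influence strengths and activation thresholds are unknown, so an
  influence need not take effect.
- **C3 (0-changes justified)**: a non-input i with μᵗ(i) = 0 must receive
  either no nonzero influence or two *distinct edges* with opposing nonzero
  influences (the only way a sum of two influences cancels). The two edges
  may share a source: an unsigned interaction expands into exactly such a
  pair.
- **C4 (foundedness)**: every changed node must be reachable from an input
  along edges whose influence matches each step's label. Computed as a
  least fixpoint containing the inputs; it converges in at most |V| rounds.
  This filters self-justification through positive feedback loops.

Inputs are exempt from C2/C3 (their changes are externally caused) and are
trivially founded, but remain subject to C1 when measured. The four global
notions are WP = {C1,C2}, SP = +C3, FWP = {C1,C2,C4}, FSP = all four; the
admissible-labeling sets nest accordingly, so predictions can only sharpen
as constraints are added. A consequence worth noting: a non-input node
without predecessors is forced to 0 by C2 under every notion.

## Search engine

No external constraint solver is used; the engine
(`signcons._engine`) is a depth-first branch-and-bound over node labels
with three ingredients:

- **Static domain pruning** (modes with hard C2): a nonzero value with no
  predecessor able to supply it is removed, to a fixpoint; under C4 a
  stronger grounded variant keeps only values derivable from inputs
  through domain-supported chains.
- **Assignment-time viability**: when a node is labeled, its own C2/C3
  status and that of its already-labeled successors are re-checked against
  assigned predecessors plus the optimistic domains of unassigned ones;
  these checks are exact once all predecessors are labeled, so no separate
  completion check is needed. Under C4 an optimistic foundedness fixpoint
  (unassigned predecessors assumed helpful) prunes branches whose changed
  nodes can no longer be founded; at a leaf it degenerates to the exact
  C4 test.
- **Ordering**: nodes are assigned goal-first — backward breadth-first from
  every observation- or query-constrained node, then the free remainder in
  forward breadth-first order from the inputs — with value order preferring
  0. Failures of a justification chain then surface next to the decision
  that caused them. Enumeration results are sorted afterwards, so callers
  always see labelings lexicographically (sorted node ids, + < 0 < −).

Cautious prediction needs at most two satisfiability queries per node
beyond one shared witness: each successful query's full witness feeds every
node's realized-label set. The prediction map covers measured nodes too
(their entry restates or narrows the observation); evaluation statistics
later restrict to unmeasured nodes.

## Repair

**MCoS.** A repair (i, s) adds a fresh artificial input pinned to + with an
edge of sign s into i, so the added influence is *always active*: it can
justify a change (C2), found it (C4) — and also break C3 at a 0-labeled
target, which the search accounts for. "Minimal" means minimum
cardinality. Rather than iterating over repair subsets, the engine
minimizes over C1-admissible labelings the number of repairs the labeling
forces, which decomposes exactly:

  cost(μᵗ) = #C2-violations + #C3-violations + #source SCCs of the
  unfounded justification subgraph.

A C2 violation at i forces (i, μᵗ(i)); a C3 violation (all nonzero
influences of sign s) forces (i, −s); each *source* strongly connected
component of the justification graph restricted to unfounded changed nodes
needs exactly one repair, placeable at any member (the justification edges
then found the rest). Since a labeling consistent under a size-k repair set
has cost ≤ k, and a minimal cover of an optimal labeling is a minimum
repair set, min-cost equals MCoS size, and the minimum repair sets are
exactly the minimal covers of the optimal labelings — which also gives
prediction under minimal repair without enumerating repair sets: the
admissible labelings are those with optimal cost. Iterative deepening over
the cost bound makes the first feasible level provably minimal; a
configurable cap (default 32) guards runaway searches.

The inconsistency index is MCoS size divided by the number of
observations; it is 0 exactly for consistent instances.

**SCEN-FIT.** Propagation constraints (C2 and C3/C4 per the chosen notion)
are hard; the cost is the number of measured nodes whose label falls
outside the observation's admitted set (unit cost; a label inside an
uncertain observation's two-label set costs nothing). We apply the selected
notion's full constraint set uniformly, including foundedness — an
interpretation choice, stated here because corrected labelings could
alternatively be exempted from C4.

**MCoS vs SCEN-FIT.** When C3 is inactive (WP, FWP), MCoS never exceeds
SCEN-FIT: repairing each mismatched observation of a SCEN-FIT-optimal
labeling only ever adds justifications. With C3 active this construction
fails — the always-on artificial influence can break a neighboring
0-justification — and the inequality is genuinely false: on the two-node
positive loop a→b→a with a negative self-loop on a, no inputs, and
observations {a: +, b: u−}, SCEN-FIT = 1 but MCoS = 2 under FSP (confirmed
independently by exhaustive enumeration; frozen as a regression test). The
inequality is therefore asserted only for WP/FWP.

## Evaluation

A strong prediction is a true positive against an equal certain held-out
observation; w+ accepts + or 0, w− accepts − or 0, chg accepts + or −; any
other *certain* observation is a false positive. Uncertain validation
observations are excluded from TP/FP counts — precision is defined against
certain measurements only — but appear as confusion-matrix rows; this
asymmetry is deliberate. Precision is TP/(TP+FP), overall and per class.

Information gain for n unmeasured nodes with k strong, l weak and m absent
predictions is (n·log3 − l·log2 − m·log3)/(n·log3): the log-scale shrinkage
of the 3ⁿ behavior combinations to 2ˡ·3ᵐ. It is linear in (k, l, m), 1 when
everything is pinned, 0 when nothing is.

Cross-validation draws, per sample, ⌈fraction·|S|⌉ observations without
replacement (inputs unchanged), predicts under all minimum correction sets,
and validates on the held-out rest. Recovery and information gain are
computed over all nodes unmeasured in the sample, inputs included (inputs
can carry genuine predictions — the worked example predicts its input
regulator). Aggregation is an unweighted mean over samples; samples with
nothing countable are skipped in the precision mean; fraction 1.0 is legal
and flagged as having no validation data. All randomness derives from
`numpy.random.default_rng([seed, sample_index])`, so reports are
reproducible bit for bit.

The shuffle null permutes the observed labels among the measured nodes —
preserving the sign distribution exactly — and compares inconsistency
indices. For a single profile the reported p-value is the empirical
quantile (1 + #{null ≤ real})/(1 + n_shuffles); across a collection of
profiles, per-profile real and mean-null indices go into a Wilcoxon
signed-rank test (delegated to scipy). A profile with a single distinct
label is flagged degenerate: its null collapses.

## Synthetic data

`sample_instance` emulates a steady-state shift experiment at desk scale.
Defaults: 30 nodes with 2.6 edges per node and 85 % of nodes observed
(matching the node/edge/coverage proportions of a curated bacterial
transcriptional network confronted with microarray profiles), 35 % of
edges inhibitory, 10 % of observations softened into the uncertain bands,
no observation noise. Inputs are the predecessor-free nodes (plus extras
with probability `p_input`); when none exists, one node is designated
perturbed — an unperturbed steady-state shift experiment is not a
meaningful condition. Inputs are pinned to random nonzero labels and the
remaining labels are drawn by the consistency engine with randomized
branching (forward assignment order, each change justified by an
already-founded predecessor), so the hidden labeling is a valid witness
under any notion including FSP — forward simulation alone could not
guarantee C3. Observations report the hidden label, softened or flipped
per the configured rates.

What passing tests on this generator do show: the constraint semantics,
search, repair and evaluation machinery are mutually consistent and sound
against a known ground truth. What they do not show: performance on real
expression data, where discretization thresholds, unmodeled regulators,
post-transcriptional effects and correlated noise dominate; genome-scale
inputs (thousands of nodes) also demand a dedicated solver backend rather
than this engine. Reported precisions on synthetic noiseless data are 1.0
by construction and are a soundness check, not a performance estimate.

## Numerical and determinism choices

Problem sizes in the test suite and acceptance script (≤ 8 nodes for
exhaustive cross-checks, 20–30 for pipeline runs, hundreds of seeds) were
chosen so the exhaustive reference stays enumerable and full runs complete
in seconds to minutes. Labelings are enumerated in a fixed lexicographic
order; repair sets are sorted; JSON reports are byte-stable for fixed
inputs and seed. Enumeration guards default to 10⁶ labelings and raise
explicitly rather than truncate silently. Ties in value order are broken
as + < 0 < −.

## Known limitations

- MCoS set *enumeration* (not size) can be exponential on large
  inconsistent instances; `collect_sets=False` computes size and index
  only, and prediction under repair never enumerates sets.
- The engine's worst case is exponential; the goal-directed ordering and
  foundedness pruning keep the studied sizes fast, but adversarial dense
  instances with sparse observations can still be slow.
- Single global thresholds for all species are a known simplification of
  discretization; per-gene or variance-aware schemes are out of scope.
- Multi-experiment network optimization (editing topology against many
  profiles at once) and transient, non-steady-state semantics are out of
  scope.
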
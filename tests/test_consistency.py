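"""Constraint evaluation, foundedness, and global consistency checking."""

import pytest

from signcons.bruteforce import enumerate_labelings_bf, is_consistent_bf
from signcons.consistency import (
    Violation,
    enumerate_labelings,
    exists_labeling,
    founded_nodes,
    is_consistent,
    violations,
)
from signcons.model import (
    ExperimentalProfile,
    InteractionGraph,
    LimitExceededError,
    NodeLabel,
    Notion,
    ObsLabel,
    Sign,
)
from signcons.synth import random_test_instance

UP, ZERO, DOWN = NodeLabel.UP, NodeLabel.ZERO, NodeLabel.DOWN


class TestViolations:
    def test_propagation_along_one_edge_is_clean(self, g1):
        g, p = g1
        assert violations(g, p, {"A": UP, "B": UP}, Notion.WP) == frozenset()

    def test_broken_observation_and_unjustified_change(self, g1):
        g, p = g1
        out = violations(g, p, {"A": ZERO, "B": UP}, Notion.WP)
        assert out == {Violation("A", "C1"), Violation("B", "C2")}

    def test_single_nonzero_influence_forbids_zero_under_sp(self):
        g = InteractionGraph([("B", "D", Sign.PLUS)])
        p = ExperimentalProfile(inputs={"B"})
        labeling = {"B": UP, "D": ZERO}
        assert violations(g, p, labeling, Notion.SP) == {Violation("D", "C3")}
        assert violations(g, p, labeling, Notion.WP) == frozenset()

    def test_opposing_influences_justify_zero_under_sp(self):
        g = InteractionGraph(
            [("J1", "I", Sign.PLUS), ("J2", "I", Sign.MINUS)]
        )
        p = ExperimentalProfile(inputs={"J1", "J2"})
        labeling = {"J1": UP, "J2": UP, "I": ZERO}
        assert violations(g, p, labeling, Notion.SP) == frozenset()

    def test_parallel_opposite_edges_count_as_opposing_pair(self):
        # an unsigned interaction is encoded as two parallel edges; a
        # changed source then justifies a 0-change at the target
        g = InteractionGraph(
            [("J", "I", Sign.PLUS), ("J", "I", Sign.MINUS)]
        )
        p = ExperimentalProfile(inputs={"J"})
        assert violations(g, p, {"J": UP, "I": ZERO}, Notion.SP) == frozenset()

    def test_inputs_exempt_from_c2_c3_but_not_c1(self):
        g = InteractionGraph([], nodes=["I"])
        p = ExperimentalProfile(discrete={"I": ObsLabel.ZERO}, inputs={"I"})
        assert violations(g, p, {"I": UP}, Notion.FSP) == {Violation("I", "C1")}
        p2 = ExperimentalProfile(discrete={"I": ObsLabel.UP}, inputs={"I"})
        assert violations(g, p2, {"I": UP}, Notion.FSP) == frozenset()

    def test_partial_labeling_rejected(self, g1):
        g, p = g1
        with pytest.raises(ValueError, match="not total"):
            violations(g, p, {"A": UP}, Notion.WP)


class TestFoundedNodes:
    G3_EDGES = [
        ("A", "B", Sign.PLUS),
        ("B", "C", Sign.PLUS),
        ("C", "B", Sign.PLUS),
        ("C", "D", Sign.PLUS),
    ]

    def test_self_justifying_loop_is_unfounded(self):
        g = InteractionGraph(self.G3_EDGES)
        labeling = {"A": ZERO, "B": UP, "C": UP, "D": UP}
        assert founded_nodes(g, labeling, {"A"}) == {"A"}

    def test_chain_of_matching_influences_is_founded(self):
        g = InteractionGraph(self.G3_EDGES)
        labeling = {"A": UP, "B": UP, "C": UP, "D": UP}
        assert founded_nodes(g, labeling, {"A"}) == {"A", "B", "C", "D"}

    def test_inputs_always_founded(self):
        g = InteractionGraph([], nodes=["X"])
        assert founded_nodes(g, {"X": UP}, {"X"}) == {"X"}
        assert founded_nodes(g, {"X": ZERO}, {"X"}) == {"X"}

    def test_monotone_in_inputs_and_bounded_rounds(self):
        g = InteractionGraph(self.G3_EDGES)
        labeling = {"A": ZERO, "B": UP, "C": UP, "D": UP}
        small = founded_nodes(g, labeling, {"A"})
        large = founded_nodes(g, labeling, {"A", "B"})
        assert small <= large
        assert large == {"A", "B", "C", "D"}


class TestGlobalConsistency:
    def test_two_node_negative_loop_globally_inconsistent(self, g2):
        g, p = g2
        assert not is_consistent(g, p, Notion.WP)

    def test_positive_loop_self_justification_filtered_by_foundedness(self, g3):
        g, p = g3
        assert is_consistent(g, p, Notion.SP)
        assert not is_consistent(g, p, Notion.FSP)

    def test_single_edge_consistent_under_all_notions(self, g1):
        g, p = g1
        for notion in Notion:
            assert is_consistent(g, p, notion)

    def test_isolated_unmeasured_node_preserves_consistency(self, g1):
        g, p = g1
        g_plus = InteractionGraph(g.edges, nodes=list(g.nodes) + ["lonely"])
        for notion in Notion:
            assert is_consistent(g_plus, p, notion)


class TestEnumeration:
    def test_unique_labeling_on_chain(self, g1):
        g, p = g1
        assert list(enumerate_labelings(g, p, Notion.WP)) == [{"A": UP, "B": UP}]

    def test_positive_loop_unique_sp_labeling(self, g3):
        g, p = g3
        labs = list(enumerate_labelings(g, p, Notion.SP))
        assert labs == [{"A": ZERO, "B": UP, "C": UP, "D": UP}]

    def test_change_in_loop_must_propagate_even_under_wp(self, g3):
        # the increase observed at D can only be justified through C and B,
        # so a 0-change at B would leave C unjustified: one WP labeling
        labs = list(enumerate_labelings(*g3, Notion.WP))
        assert labs == [{"A": ZERO, "B": UP, "C": UP, "D": UP}]
        assert not exists_labeling(*g3, Notion.WP, pinned={"B": ZERO})

    def test_lexicographic_order_and_no_duplicates(self, posloop):
        g, p = posloop
        labs = list(enumerate_labelings(g, p, Notion.FWP))
        keys = [tuple((lab[n] != UP, lab[n] == DOWN) for n in g.nodes) for lab in labs]
        assert keys == sorted(keys)
        assert len({tuple(lab.items()) for lab in labs}) == len(labs)

    def test_limit_guard(self, posloop):
        g, p = posloop
        with pytest.raises(LimitExceededError):
            list(enumerate_labelings(g, p, Notion.WP, limit=3))

    def test_forced_zero_for_predecessor_free_non_inputs(self):
        # a non-input node without predecessors can never justify a change
        g = InteractionGraph([("A", "B", Sign.PLUS)], nodes=["orphan"])
        p = ExperimentalProfile(discrete={"A": ObsLabel.UP, "B": ObsLabel.UP},
                                inputs={"A"})
        for notion in Notion:
            for lab in enumerate_labelings(g, p, notion):
                assert lab["orphan"] == ZERO


class TestExistsLabeling:
    def test_pinned_zero_in_forced_chain(self, g3):
        g, p = g3
        assert not exists_labeling(g, p, Notion.SP, pinned={"B": ZERO})

    def test_empty_pin_equals_consistency(self, g2, g1):
        assert exists_labeling(*g1, Notion.FSP, pinned={}) is True
        assert exists_labeling(*g2, Notion.WP, pinned={}) is False

    def test_unknown_pinned_node_rejected(self, g1):
        g, p = g1
        with pytest.raises(KeyError):
            exists_labeling(g, p, Notion.WP, pinned={"nope": UP})


class TestNotionNesting:
    def test_labeling_sets_nest_across_notions(self, posloop):
        g, p = posloop
        sets = {
            notion: {tuple(sorted(lab.items()))
                     for lab in enumerate_labelings(g, p, notion)}
            for notion in Notion
        }
        assert sets[Notion.FSP] < sets[Notion.SP] < sets[Notion.WP]
        assert sets[Notion.FSP] < sets[Notion.FWP] < sets[Notion.WP]


@pytest.mark.parametrize("seed", range(60))
def test_engine_agrees_with_exhaustive_reference(seed):
    """Search backend vs direct 3^|V| evaluation of the constraint
    definitions: verdicts and full labeling sets must coincide."""
    graph, profile = random_test_instance(seed)
    notion = list(Notion)[seed % 4]
    engine = list(enumerate_labelings(graph, profile, notion))
    reference = enumerate_labelings_bf(graph, profile, notion)
    assert engine == reference
    assert is_consistent(graph, profile, notion) == is_consistent_bf(
        graph, profile, notion
    )
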
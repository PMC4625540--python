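"""Repair: minimum correction sets, SCEN-FIT, prediction under repair."""

import pytest

from signcons.bruteforce import (
    enumerate_labelings_bf,
    is_consistent_bf,
    mcos_bf,
    scenfit_bf,
)
from signcons.consistency import is_consistent
from signcons.model import (
    ExperimentalProfile,
    InteractionGraph,
    NodeLabel,
    Notion,
    ObsLabel,
    Sign,
)
from signcons.predict import PredLabel, classify, predict
from signcons.repair import (
    apply_repair,
    inconsistency_index,
    is_artificial,
    mcos,
    predict_under_mcos,
    repaired_instance,
    scenfit,
)
from signcons.synth import random_test_instance

P, M = Sign.PLUS, Sign.MINUS


class TestApplyRepair:
    def test_single_repair_adds_node_and_edge(self, g4):
        g, _p = g4
        g2 = apply_repair(g, frozenset({("A", P)}))
        assert len(g2) == len(g) + 1
        assert len(g2.edges) == len(g.edges) + 1
        (new,) = [n for n in g2.nodes if n not in g.nodes]
        assert is_artificial(new)
        assert (new, P) in g2.predecessors("A")

    def test_empty_repair_is_identity(self, g4):
        g, _p = g4
        assert apply_repair(g, frozenset()) == g

    def test_two_repairs_two_artificial_influences(self, g4):
        g, _p = g4
        g2 = apply_repair(g, frozenset({("A", P), ("B", M)}))
        assert len(g2) == len(g) + 2
        fresh = [n for n in g2.nodes if is_artificial(n)]
        assert len(fresh) == 2

    def test_unknown_target_rejected(self, g4):
        g, _p = g4
        with pytest.raises(KeyError):
            apply_repair(g, frozenset({("nope", P)}))

    def test_repaired_instance_pins_artificial_nodes(self, g4):
        g, p = g4
        g2, p2 = repaired_instance(g, p, frozenset({("A", P)}))
        art = [n for n in g2.nodes if is_artificial(n)]
        assert all(p2.discrete[a] is ObsLabel.UP for a in art)
        assert set(art) <= p2.inputs


class TestMcos:
    def test_opposite_observations_two_singleton_repairs(self, g4):
        g, p = g4
        result = mcos(g, p, Notion.FSP)
        assert result.size == 1
        assert set(result.sets) == {
            frozenset({("A", P)}),
            frozenset({("B", M)}),
        }
        assert result.index == pytest.approx(0.5)

    def test_consistent_instance_empty_repair(self, g1):
        g, p = g1
        result = mcos(g, p, Notion.FSP)
        assert result.size == 0
        assert result.sets == (frozenset(),)
        assert result.index == 0.0

    def test_unfounded_loop_three_alternative_anchors(self, g3):
        g, p = g3
        result = mcos(g, p, Notion.FSP)
        assert result.size == 1
        assert set(result.sets) == {
            frozenset({("B", P)}),
            frozenset({("C", P)}),
            frozenset({("D", P)}),
        }

    def test_every_minimum_set_restores_consistency(self, g3, g4):
        for g, p in (g3, g4):
            result = mcos(g, p, Notion.FSP)
            for rs in result.sets:
                assert is_consistent(*repaired_instance(g, p, rs), Notion.FSP)

    def test_removing_an_observation_never_raises_size(self, g4):
        g, p = g4
        full = mcos(g, p, Notion.FSP, collect_sets=False).size
        for node in p.measured:
            reduced = p.subset(p.measured - {node})
            assert mcos(g, reduced, Notion.FSP, collect_sets=False).size <= full


class TestInconsistencyIndex:
    def test_worked_example_half(self, g4):
        assert inconsistency_index(*g4, Notion.FSP) == pytest.approx(0.5)

    def test_consistent_is_zero(self, g1):
        assert inconsistency_index(*g1, Notion.FSP) == 0.0

    def test_no_observations_rejected(self):
        g = InteractionGraph([("A", "B", P)])
        with pytest.raises(ValueError, match="no observations"):
            inconsistency_index(g, ExperimentalProfile(inputs={"A"}), Notion.FSP)


class TestPredictUnderMcos:
    def test_excluded_middle_for_shared_regulator(self, g4):
        # C drives A up or B down under the two minimal repairs, never 0
        pm = predict_under_mcos(*g4, Notion.FSP)
        assert pm["C"] is PredLabel.CHANGE
        assert not any(is_artificial(n) for n in pm)

    def test_loop_anchor_weak_increase(self, g3):
        # repairs at B or C force C=+, the repair at D lets C rest at 0
        pm = predict_under_mcos(*g3, Notion.FSP)
        assert pm["C"] is PredLabel.WEAK_UP
        assert pm["D"] is PredLabel.UP

    def test_degenerates_to_predict_on_consistent_instances(self, g1, posloop):
        for g, p in (g1, posloop):
            assert predict_under_mcos(g, p, Notion.FSP) == predict(
                g, p, Notion.FSP
            )


class TestScenfit:
    def test_one_correction_for_opposite_twins(self, g4):
        corrections, witnesses = scenfit(*g4, Notion.FSP)
        assert corrections == 1
        assert len(witnesses) == 2  # C=+ mislabels B; C=- mislabels A

    def test_negative_loop_needs_two_corrections(self, g2):
        corrections, _w = scenfit(*g2, Notion.WP)
        assert corrections == 2

    def test_consistent_instance_zero_corrections(self, g1):
        corrections, witnesses = scenfit(*g1, Notion.FSP)
        assert corrections == 0
        assert witnesses == ({"A": NodeLabel.UP, "B": NodeLabel.UP},)


def test_mcos_can_exceed_scenfit_under_strong_propagation():
    """With C3 active the always-on artificial influence of a repair can
    itself break a neighboring 0-justification, so the repair count may
    exceed the observation-correction count.  Frozen counterexample,
    confirmed by the exhaustive reference."""
    g = InteractionGraph([("a", "a", M), ("a", "b", P), ("b", "a", P)])
    p = ExperimentalProfile(
        discrete={"a": ObsLabel.UP, "b": ObsLabel.UNCERTAIN_DOWN}
    )
    assert scenfit(g, p, Notion.FSP)[0] == 1
    assert mcos(g, p, Notion.FSP, collect_sets=False).size == 2
    assert scenfit_bf(g, p, Notion.FSP)[0] == 1
    assert mcos_bf(g, p, Notion.FSP)[0] == 2


@pytest.mark.parametrize("seed", range(40))
def test_repair_operations_agree_with_exhaustive_reference(seed):
    """Engine vs exhaustive subset/enumeration oracles, plus the relations
    that hold by construction: minimum sets repair, size zero iff
    consistent, WP never needs more repairs than FSP, and (without C3)
    repairs never exceed observation corrections."""
    graph, profile = random_test_instance(seed, max_nodes=6)
    notion = list(Notion)[seed % 4]

    result = mcos(graph, profile, notion, max_size=6)
    k_ref, sets_ref = mcos_bf(graph, profile, notion, max_size=6)
    assert result.size == k_ref
    assert set(result.sets) == sets_ref

    corrections, witnesses = scenfit(graph, profile, notion)
    c_ref, w_ref = scenfit_bf(graph, profile, notion)
    assert corrections == c_ref
    assert list(witnesses) == w_ref

    assert (result.size == 0) == is_consistent(graph, profile, notion)
    if not notion.uses_c3:
        assert result.size <= corrections
    wp_size = mcos(graph, profile, Notion.WP, max_size=6, collect_sets=False).size
    fsp_size = mcos(graph, profile, Notion.FSP, max_size=6, collect_sets=False).size
    assert wp_size <= fsp_size

    # prediction under repair equals its definition: consequences over all
    # consistent labelings of all minimally repaired instances
    realized = {node: set() for node in graph.nodes}
    for rs in result.sets:
        g2, p2 = repaired_instance(graph, profile, rs)
        assert is_consistent_bf(g2, p2, notion)
        for lab in enumerate_labelings_bf(g2, p2, notion):
            for node in graph.nodes:
                realized[node].add(lab[node])
    expected = {node: classify(vals) for node, vals in realized.items()}
    assert predict_under_mcos(graph, profile, notion) == expected
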
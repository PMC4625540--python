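"""Evaluation metrics: recovery, information gain, precision, confusion,
cross-validation and the shuffle null."""


import numpy as np
import pytest

from signcons.metrics import (
    EvalReport,
    PredictionCounts,
    confusion_matrix,
    crossval,
    information_gain,
    null_distribution,
    paired_null_test,
    precision,
    recovery_rate,
    validate_prediction,
)
from signcons.model import ExperimentalProfile, Notion, ObsLabel
from signcons.predict import PredLabel
from signcons.synth import SynthConfig, sample_instance


class TestRecoveryRate:
    def test_counts_any_non_no_prediction(self):
        pm = {"B": PredLabel.UP, "C": PredLabel.NO}
        assert recovery_rate(pm, {"B", "C"}) == 0.5

    def test_all_no_is_zero(self):
        pm = {"B": PredLabel.NO, "C": PredLabel.NO}
        assert recovery_rate(pm, {"B", "C"}) == 0.0

    def test_weak_counts_as_prediction(self):
        assert recovery_rate({"B": PredLabel.WEAK_UP}, {"B"}) == 1.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            recovery_rate({}, set())


class TestInformationGain:
    def test_all_strong_is_one(self):
        assert information_gain(PredictionCounts(100, 100, 0, 0)) == 1.0

    def test_all_unpredicted_is_zero(self):
        assert information_gain(PredictionCounts(100, 0, 0, 100)) == 0.0

    @pytest.mark.parametrize(
        "l, gain",  # weak-prediction shares and the gains they yield
        [(774, 0.0286), (1314, 0.0485), (2899, 0.1070)],
    )
    def test_weak_share_to_gain(self, l, gain):
        counts = PredictionCounts(n=10000, k=0, l=l, m=10000 - l)
        assert information_gain(counts) == pytest.approx(gain, abs=5e-5)

    def test_linear_in_counts(self):
        # the gain of k strong plus l weak predictions is the sum of the
        # gains of each group alone
        combined = information_gain(PredictionCounts(1000, 120, 340, 540))
        strong = information_gain(PredictionCounts(1000, 120, 0, 880))
        weak = information_gain(PredictionCounts(1000, 0, 340, 660))
        assert combined == pytest.approx(strong + weak)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            PredictionCounts(10, 5, 5, 5)
        with pytest.raises(ValueError):
            information_gain(PredictionCounts(0, 0, 0, 0))


class TestValidatePrediction:
    @pytest.mark.parametrize(
        "pred, obs, verdict",
        [
            (PredLabel.UP, ObsLabel.UP, "TP"),
            (PredLabel.UP, ObsLabel.ZERO, "FP"),
            (PredLabel.ZERO, ObsLabel.ZERO, "TP"),
            (PredLabel.WEAK_UP, ObsLabel.ZERO, "TP"),
            (PredLabel.WEAK_UP, ObsLabel.UP, "TP"),
            (PredLabel.WEAK_UP, ObsLabel.DOWN, "FP"),
            (PredLabel.WEAK_DOWN, ObsLabel.DOWN, "TP"),
            (PredLabel.WEAK_DOWN, ObsLabel.UP, "FP"),
            (PredLabel.CHANGE, ObsLabel.UP, "TP"),
            (PredLabel.CHANGE, ObsLabel.DOWN, "TP"),
            (PredLabel.CHANGE, ObsLabel.ZERO, "FP"),
            (PredLabel.CHANGE, ObsLabel.UNCERTAIN_UP, "uncounted"),
            (PredLabel.UP, ObsLabel.UNCERTAIN_DOWN, "uncounted"),
        ],
    )
    def test_verdicts(self, pred, obs, verdict):
        assert validate_prediction(pred, obs) == verdict

    def test_no_is_not_a_prediction(self):
        with pytest.raises(ValueError):
            validate_prediction(PredLabel.NO, ObsLabel.UP)


class TestPrecision:
    def test_single_true_positive(self):
        overall, by_class = precision({"B": PredLabel.UP}, {"B": ObsLabel.UP})
        assert overall == 1.0
        assert by_class == {PredLabel.UP: 1.0}

    def test_mixed(self):
        overall, by_class = precision(
            {"B": PredLabel.UP, "C": PredLabel.WEAK_UP},
            {"B": ObsLabel.UP, "C": ObsLabel.DOWN},
        )
        assert overall == 0.5
        assert by_class[PredLabel.WEAK_UP] == 0.0

    def test_uncertain_only_validation_rejected(self):
        with pytest.raises(ValueError):
            precision({"B": PredLabel.WEAK_UP}, {"B": ObsLabel.UNCERTAIN_DOWN})

    def test_removing_a_false_positive_never_hurts(self):
        pm = {"B": PredLabel.UP, "C": PredLabel.UP, "D": PredLabel.DOWN}
        val = {"B": ObsLabel.UP, "C": ObsLabel.DOWN, "D": ObsLabel.DOWN}
        with_fp, _ = precision(pm, val)
        without_fp, _ = precision(pm, {k: v for k, v in val.items() if k != "C"})
        assert without_fp >= with_fp


class TestConfusionMatrix:
    def test_single_cell(self):
        mat = confusion_matrix({"B": PredLabel.UP}, {"B": ObsLabel.UP})
        assert mat.loc["+", "+"] == 1
        assert mat.to_numpy().sum() == 1

    def test_no_prediction_column(self):
        mat = confusion_matrix({"B": PredLabel.NO}, {"B": ObsLabel.ZERO})
        assert mat.loc["0", "no"] == 1

    def test_cell_sum_equals_validated_nodes(self):
        pm = {"A": PredLabel.UP, "B": PredLabel.NO, "C": PredLabel.WEAK_DOWN}
        val = {"A": ObsLabel.UNCERTAIN_UP, "B": ObsLabel.ZERO,
               "C": ObsLabel.DOWN, "ghost": ObsLabel.UP}
        mat = confusion_matrix(pm, val)
        assert mat.to_numpy().sum() == 3


@pytest.fixture(scope="module")
def synthetic():
    return sample_instance(SynthConfig(n_nodes=20, n_edges=52, seed=11))


class TestCrossval:
    def test_deterministic_under_seed(self, synthetic):
        g, _h, p = synthetic
        a = crossval(g, p, 0.2, 3, Notion.FSP, seed=5)
        b = crossval(g, p, 0.2, 3, Notion.FSP, seed=5)
        assert a.samples.equals(b.samples)
        assert a.recovery == b.recovery and a.info_gain == b.info_gain

    def test_noiseless_profiles_validate_perfectly(self, synthetic):
        g, _h, p = synthetic
        report = crossval(g, p, 0.2, 4, Notion.FSP, seed=2)
        assert report.precision_overall == 1.0
        assert 0.0 <= report.recovery <= 1.0
        assert 0.0 <= report.info_gain <= 1.0

    def test_full_fraction_flags_missing_validation(self, synthetic):
        g, _h, p = synthetic
        report = crossval(g, p, 1.0, 1, Notion.FSP, seed=0)
        assert report.no_validation
        assert report.precision_overall is None

    def test_more_data_more_recovery_on_average(self, synthetic):
        g, _h, p = synthetic
        low = crossval(g, p, 0.1, 4, Notion.FSP, seed=3).recovery
        high = crossval(g, p, 0.6, 4, Notion.FSP, seed=3).recovery
        assert low <= high + 1e-9

    def test_fraction_out_of_range(self, synthetic):
        g, _h, p = synthetic
        with pytest.raises(ValueError):
            crossval(g, p, 0.0, 1, Notion.FSP, seed=0)

    def test_report_serialization(self, synthetic):
        g, _h, p = synthetic
        report = crossval(g, p, 0.3, 2, Notion.FSP, seed=1)
        assert isinstance(report, EvalReport)
        payload = report.to_json_dict()
        assert payload["notion"] == "FSP"
        tsv = report.to_tsv()
        assert tsv.splitlines()[0].startswith("sample")
        assert tsv.splitlines()[-1].startswith("mean")


class TestNullDistribution:
    def test_shuffles_preserve_sign_distribution(self, synthetic):
        g, _h, p = synthetic
        res = null_distribution(g, p, 4, Notion.FSP, seed=9)
        assert res.real_index == 0.0  # noiseless data fit the topology
        assert all(0.0 <= v <= 1.0 for v in res.shuffled_indices)
        assert len(res.shuffled_indices) == 4

    def test_real_data_beat_the_null(self, synthetic):
        g, _h, p = synthetic
        res = null_distribution(g, p, 19, Notion.FSP, seed=1)
        assert np.mean(res.shuffled_indices) > res.real_index
        assert res.p_value == pytest.approx(1 / 20)

    def test_zero_shuffles_rejected(self, synthetic):
        g, _h, p = synthetic
        with pytest.raises(ValueError):
            null_distribution(g, p, 0, Notion.FSP, seed=0)

    def test_constant_profile_flagged_degenerate(self):
        g, _h, _p = sample_instance(SynthConfig(n_nodes=5, n_edges=4, seed=3))
        flat = ExperimentalProfile(
            discrete={n: ObsLabel.ZERO for n in list(g.nodes)[:3]}
        )
        res = null_distribution(g, flat, 3, Notion.WP, seed=0)
        assert res.degenerate
        assert len(set(res.shuffled_indices)) == 1

    def test_paired_rank_test_contract(self):
        real = [0.0, 0.01, 0.02, 0.0, 0.03, 0.01, 0.02, 0.015]
        null = [0.3, 0.28, 0.31, 0.25, 0.33, 0.29, 0.27, 0.3]
        p = paired_null_test(real, null)
        assert 0 < p < 0.05
        with pytest.raises(ValueError):
            paired_null_test([0.1], [0.2, 0.3])
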
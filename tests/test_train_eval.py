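"""Training schedule, cross-validation folds, and the scoring metric suite."""

import numpy as np
import pytest
import sklearn.metrics as skm

from somnograph.benchmarks import SLEEP_EDF_CONFUSION
from somnograph.network import NetworkConfig, SleepStageNetwork
from somnograph.train_eval import (TrainConfig, confusion, evaluate,
                                   learning_rate_at, read_confusion_tsv,
                                   subject_folds, train, write_confusion_tsv)


class TestSchedule:
    @pytest.mark.parametrize("epoch,expected", [
        (1, 1e-3), (30, 1e-4), (60, 1e-5), (90, 1e-6), (119, 1e-6)])
    def test_reference_decay_rule(self, epoch, expected):
        assert learning_rate_at(epoch, TrainConfig()) == pytest.approx(expected)

    def test_unsorted_steps_rejected(self):
        with pytest.raises(ValueError, match="ascending"):
            TrainConfig(lr_step_epochs=(60, 30))


class TestFolds:
    def test_ten_subjects_ten_disjoint_folds(self):
        ids = np.repeat([f"s{i}" for i in range(10)], 3)
        folds = subject_folds(ids, 10)
        assert len(folds) == 10
        covered = np.concatenate([te for _, te in folds])
        assert sorted(covered.tolist()) == list(range(30))
        for tr, te in folds:
            assert set(tr) & set(te) == set()
            assert len(set(ids[te])) == 1   # one subject per test fold

    def test_leave_one_subject_out_twenty(self):
        ids = [f"s{i:02d}" for i in range(20)]
        folds = subject_folds(ids, 20)
        assert len(folds) == 20
        assert all(len(te) == 1 for _, te in folds)

    def test_more_folds_than_subjects_rejected(self):
        with pytest.raises(ValueError):
            subject_folds(["a", "b", "c"], 5)


class TestConfusion:
    def test_diagonal_for_perfect_agreement(self):
        cm = confusion([0, 1, 2, 3, 4], [0, 1, 2, 3, 4])
        np.testing.assert_array_equal(cm, np.eye(5, dtype=int))

    def test_grand_total_conserved(self, rng):
        y_true = rng.integers(0, 5, 137)
        y_pred = rng.integers(0, 5, 137)
        assert confusion(y_true, y_pred).sum() == 137

    def test_benchmark_row_totals(self):
        np.testing.assert_array_equal(
            SLEEP_EDF_CONFUSION.sum(axis=1),
            [7927, 2804, 17799, 5703, 7717])


class TestEvaluate:
    def test_perfect_matrix_all_ones(self):
        rep = evaluate(np.eye(5, dtype=int) * 10)
        assert rep.accuracy == rep.macro_f == rep.kappa == 1.0

    def test_constant_predictor_chance_kappa(self):
        cm = np.zeros((5, 5), dtype=int)
        cm[:, 0] = 20   # everything predicted W, uniform truth
        rep = evaluate(cm)
        assert rep.accuracy == pytest.approx(0.2)
        assert rep.kappa == pytest.approx(0.0)

    def test_cross_check_against_sklearn(self, rng):
        y_true = rng.integers(0, 5, 400)
        y_pred = np.where(rng.random(400) < 0.7, y_true,
                          rng.integers(0, 5, 400))
        rep = evaluate(confusion(y_true, y_pred))
        assert rep.accuracy == pytest.approx(skm.accuracy_score(y_true, y_pred))
        assert rep.kappa == pytest.approx(
            skm.cohen_kappa_score(y_true, y_pred))
        assert rep.macro_f == pytest.approx(
            skm.f1_score(y_true, y_pred, average="macro"))
        assert rep.macro_precision == pytest.approx(
            skm.precision_score(y_true, y_pred, average="macro"))
        assert rep.macro_recall == pytest.approx(
            skm.recall_score(y_true, y_pred, average="macro"))

    def test_kappa_invariant_under_class_relabeling(self, rng):
        cm = rng.integers(0, 50, (5, 5))
        perm = rng.permutation(5)
        assert evaluate(cm[np.ix_(perm, perm)]).kappa == pytest.approx(
            evaluate(cm).kappa)

    def test_macro_metrics_change_under_prevalence_rescaling(self):
        # negative control: macro averages are prevalence-sensitive for
        # imbalanced matrices
        cm = np.array([[80, 20], [10, 90]])
        scaled = cm.copy()
        scaled[0] *= 5
        a = evaluate(cm, class_names=("a", "b"))
        b = evaluate(scaled, class_names=("a", "b"))
        assert abs(a.macro_f - b.macro_f) > 1e-3

    def test_empty_class_flagged_zero(self):
        cm = np.zeros((5, 5), dtype=int)
        cm[0, 0] = 10
        cm[2, 2] = 5
        rep = evaluate(cm)
        assert "N1" in rep.empty_classes
        assert rep.precision["N1"] == 0.0 and rep.recall["N1"] == 0.0

    def test_tsv_round_trip(self, tmp_path):
        p = write_confusion_tsv(tmp_path / "cm.tsv", SLEEP_EDF_CONFUSION)
        cm, names = read_confusion_tsv(p)
        np.testing.assert_array_equal(cm, SLEEP_EDF_CONFUSION)
        assert names == ["W", "N1", "N2", "N3", "R"]


@pytest.fixture(scope="module")
def separable_contexts():
    """60 easily separable context blocks: class-specific band patterns."""
    rng = np.random.default_rng(42)
    x = np.zeros((60, 5, 5, 6))
    y = np.repeat(np.arange(5), 12)
    for i, cls in enumerate(y):
        x[i, cls] = 3.0           # band `cls` lights up everywhere
    x += 0.3 * rng.standard_normal(x.shape)
    return x, y


class TestTraining:
    def test_overfits_separable_set(self, isruc_graph, separable_contexts):
        x, y = separable_contexts
        cfg = NetworkConfig(n_electrodes=6, channel_plan=(16,), reduction=2)
        model = SleepStageNetwork(cfg, isruc_graph, seed=0)
        result = train(model, x, y,
                       TrainConfig(epochs=120, seed=0, batch_size=16))
        assert len(result.loss_trace) == 120
        assert result.final_train_accuracy >= 0.95
        # the recorded schedule follows the stepped decay rule
        assert result.lr_trace[0] == pytest.approx(1e-3)
        assert result.lr_trace[95] == pytest.approx(1e-6)

    def test_nan_input_aborts_with_diagnostic(self, isruc_graph,
                                              separable_contexts):
        x, y = separable_contexts
        x = x.copy()
        x[0, 0, 0, 0] = np.nan
        cfg = NetworkConfig(n_electrodes=6, channel_plan=(8,), reduction=2)
        model = SleepStageNetwork(cfg, isruc_graph, seed=0)
        with pytest.raises(RuntimeError, match="diverged"):
            train(model, x, y, TrainConfig(epochs=1, seed=0))

    def test_class_weighted_loss_runs(self, isruc_graph, separable_contexts):
        x, y = separable_contexts
        cfg = NetworkConfig(n_electrodes=6, channel_plan=(8,), reduction=2)
        model = SleepStageNetwork(cfg, isruc_graph, seed=0)
        result = train(model, x, y, TrainConfig(
            epochs=2, seed=0, class_weighting="inverse"))
        assert np.isfinite(result.loss_trace).all()

    def test_fixed_seed_reproducible_trace(self, isruc_graph,
                                           separable_contexts):
        x, y = separable_contexts
        cfg = NetworkConfig(n_electrodes=6, channel_plan=(8,), reduction=2)
        traces = []
        for _ in range(2):
            model = SleepStageNetwork(cfg, isruc_graph, seed=3)
            traces.append(train(model, x, y,
                                TrainConfig(epochs=3, seed=3)).loss_trace)
        np.testing.assert_array_equal(traces[0], traces[1])
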
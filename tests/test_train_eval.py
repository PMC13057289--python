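"""Metrics oracles, early stopping, checkpoint/resume fidelity."""

import numpy as np
import pytest

from leaffusionnet import nn
from leaffusionnet import train_eval as te
from leaffusionnet.experiments import prepare_toy_data, train_toy_model
from leaffusionnet.nn.tensor import Tensor


class TestPrecisionRecallF1:
    def test_perfect_class(self):
        assert te.precision_recall_f1(10, 0, 0) == (1.0, 1.0, 1.0)

    def test_forced_values(self):
        p, r, f1 = te.precision_recall_f1(8, 2, 2)
        assert (p, r, f1) == (0.8, 0.8, pytest.approx(0.8))

    def test_degenerate_convention_returns_zero(self):
        assert te.precision_recall_f1(0, 0, 5) == (0.0, 0.0, 0.0)
        assert te.precision_recall_f1(0, 0, 0) == (0.0, 0.0, 0.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            te.precision_recall_f1(-1, 0, 0)

    def test_hand_worked_confusion_fixture(self):
        # 3 classes, 12 samples
        y_true = np.array([0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2])
        y_pred = np.array([0, 0, 1, 2, 1, 1, 1, 0, 2, 2, 2, 2])
        cm = te.confusion_matrix(y_true, y_pred, 3)
        np.testing.assert_array_equal(cm, [[2, 1, 1], [1, 3, 0], [0, 0, 4]])
        m = te.per_class_metrics(cm)
        np.testing.assert_allclose(m["precision"], [2 / 3, 3 / 4, 4 / 5])
        np.testing.assert_allclose(m["recall"], [2 / 4, 3 / 4, 4 / 4])
        f1 = [2 * p * r / (p + r) for p, r in
              zip([2 / 3, 3 / 4, 4 / 5], [1 / 2, 3 / 4, 1.0])]
        np.testing.assert_allclose(m["f1"], f1)
        # weighted F1 identity: sum_k (n_k/N) F1_k
        weights = cm.sum(1) / cm.sum()
        assert (weights * m["f1"]).sum() == pytest.approx(
            np.dot([4 / 12, 4 / 12, 4 / 12], f1))


def mann_whitney_auc(scores_pos, scores_neg):
    """Exhaustive pair-counting AUC oracle."""
    wins = ties = 0
    for sp in scores_pos:
        for sn in scores_neg:
            wins += sp > sn
            ties += sp == sn
    return (wins + 0.5 * ties) / (len(scores_pos) * len(scores_neg))


class TestRocAuc:
    def test_matches_pair_counting_oracle_on_8_samples(self, rng):
        labels = np.array([0, 1, 0, 1, 1, 0, 1, 0])
        p1 = rng.random(8)
        scores = np.stack([1 - p1, p1], axis=1)
        auc, curves = te.roc_auc(scores, labels, "macro")
        oracle_pos = mann_whitney_auc(p1[labels == 1], p1[labels == 0])
        oracle_neg = mann_whitney_auc((1 - p1)[labels == 0], (1 - p1)[labels == 1])
        assert auc == pytest.approx((oracle_pos + oracle_neg) / 2, abs=1e-12)
        assert "0" in curves and "1" in curves

    def test_perfect_ranking_gives_unit_auc(self):
        labels = np.array([0, 1, 2, 0, 1, 2])
        scores = np.eye(3)[labels] * 0.8 + 0.1
        scores /= scores.sum(1, keepdims=True)
        assert te.roc_auc(scores, labels, "micro")[0] == pytest.approx(1.0)
        assert te.roc_auc(scores, labels, "macro")[0] == pytest.approx(1.0)

    def test_label_independent_scores_give_half(self):
        labels = np.array([0, 1, 2] * 4)
        scores = np.tile([0.5, 0.3, 0.2], (12, 1))
        assert te.roc_auc(scores, labels, "micro")[0] == pytest.approx(0.5)
        assert te.roc_auc(scores, labels, "macro")[0] == pytest.approx(0.5)

    def test_micro_invariant_to_class_relabelling(self, rng):
        labels = rng.integers(0, 3, size=30)
        scores = rng.dirichlet(np.ones(3), size=30)
        perm = np.array([2, 0, 1])  # new column order; relabel accordingly
        auc1 = te.roc_auc(scores, labels, "micro")[0]
        relabeled = np.array([int(np.where(perm == l)[0][0]) for l in labels])
        auc2 = te.roc_auc(scores[:, perm], relabeled, "micro")[0]
        assert auc1 == pytest.approx(auc2, abs=1e-12)

    def test_single_class_micro_rejected(self):
        with pytest.raises(ValueError):
            te.roc_auc(np.array([[0.6, 0.4]]), np.array([0]), "micro")

    def test_macro_skips_absent_class_with_warning(self, caplog):
        labels = np.array([0, 1, 0, 1])
        scores = np.array([[0.7, 0.2, 0.1]] * 2 + [[0.2, 0.7, 0.1]] * 2)
        with caplog.at_level("WARNING"):
            auc, curves = te.roc_auc(scores, labels, "macro")
        assert "2" not in curves


class ScriptedModel(nn.Module):
    """Minimal model whose validation probabilities are scripted per epoch,
    so early-stopping logic can be exercised deterministically."""

    def __init__(self, n_classes=2):
        super().__init__()
        from leaffusionnet.fusion_model import ModelConfig  # noqa: used for cfg shape
        self.W = Tensor(np.zeros((4, n_classes), dtype=np.float32),
                        requires_grad=True)
        self.n_eval = 0

        class _Cfg:
            n_classes = 2

            @staticmethod
            def to_dict():
                return {"scripted": True}

        self.cfg = _Cfg()

    def __call__(self, X, training=False):
        logits = nn.tensor.matmul(Tensor(X.reshape(len(X), -1)[:, :4]), self.W)
        probs = nn.tensor.softmax(logits, axis=-1)
        from leaffusionnet.fusion_model import ForwardOutput
        return ForwardOutput(probs, logits, {})

    def predict_proba(self, X, batch_size=32):
        # correct-class probability decays epoch over epoch -> val loss rises
        self.n_eval += 1
        p = max(0.9 - 0.2 * self.n_eval, 0.05)
        return np.tile([p, 1 - p], (len(X), 1))


class TestTrainingControl:
    def test_immediately_worsening_validation_stops_after_epoch_two(self):
        model = ScriptedModel()
        X = np.zeros((8, 2, 2, 1), dtype=np.float32)
        y = np.zeros(8, dtype=np.int64)
        cfg = te.TrainConfig(lr=1e-3, batch_size=4, max_epochs=10,
                             early_stop_patience=1, seed=0, augment=False,
                             restore_best=False)
        _, history = te.train(model, {"train": (X, y), "val": (X, y)}, cfg)
        assert history.epoch == [1, 2]

    def test_training_loss_trend_on_toy_profile(self, toy_runs):
        _, history, _ = toy_runs.run("full", 0)
        assert history.train_loss[4] < history.train_loss[0]

    def test_resume_with_incompatible_config_rejected(self, tmp_path):
        data = prepare_toy_data(0, n_per_class=8)
        from leaffusionnet.experiments import variant_config
        from leaffusionnet.fusion_model import LeafFusionNet
        cfg = variant_config("cnn")
        m = LeafFusionNet(cfg, seed=0)
        tcfg = te.TrainConfig(lr=2e-3, batch_size=16, max_epochs=2,
                              early_stop_patience=2, seed=0,
                              checkpoint_dir=str(tmp_path))
        te.train(m, data.splits(), tcfg, interrupt_after=1)
        other = te.TrainConfig(lr=1e-3, batch_size=16, max_epochs=2,
                               early_stop_patience=2, seed=0,
                               checkpoint_dir=str(tmp_path))
        with pytest.raises(ValueError, match="incompatible"):
            te.train(LeafFusionNet(cfg, seed=0), data.splits(), other,
                     resume=True)


class TestEvaluate:
    def test_report_identities_on_trained_model(self, toy_runs):
        model, _, report = toy_runs.run("cnn", 0)
        n = report.confusion.sum()
        data = toy_runs.data(0)
        assert n == len(data.test[0])
        assert 0.0 <= report.accuracy <= 1.0
        assert report.confusion.trace() / n == pytest.approx(report.accuracy)
        weights = report.confusion.sum(1) / n
        assert report.weighted_f1 == pytest.approx((weights * report.f1).sum())
        assert len(report.batch_loss) == len(report.batch_acc)

    def test_empty_split_rejected(self, toy_runs):
        model, _, _ = toy_runs.run("cnn", 0)
        with pytest.raises(ValueError):
            te.evaluate(model, np.zeros((0, 64, 64, 3)), np.zeros(0))
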
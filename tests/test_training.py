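"""Label tasks, worst-subtype rule, grouped CV, the training loop contracts,
majority-vote ensembling and the evaluation metrics."""

import itertools

import numpy as np
import pytest

from slidegraph import (ModelConfig, Prediction, TaskSpec, TrainConfig,
                        ensemble_predict, evaluate, grouped_kfold, map_label,
                        mean_roc, train_model, worst_subtype)
from slidegraph.synthetic import SUBTYPES
from tests.test_model import random_graph


class TestMapLabel:
    def test_healthy_is_class_zero_in_every_task(self):
        for task in ("T1", "T2", "T3"):
            assert map_label("healthy", task) == 0

    def test_examples(self):
        assert map_label("medium", "T2") == 2          # high-risk group
        assert map_label("superficial", "T3") == 1
        assert map_label("nodular", "T3") == 2
        assert map_label("high", "T3") == 4
        assert map_label("nodular", "T1") == 1

    def test_unknown_subtype_rejected(self):
        with pytest.raises(ValueError):
            map_label("weird", "T2")
        with pytest.raises(ValueError):
            map_label("healthy", "T9")

    def test_t2_is_a_coarsening_of_t3(self):
        coarsen = {0: 0, 1: 1, 2: 1, 3: 2, 4: 2}
        for s in SUBTYPES:
            assert map_label(s, "T2") == coarsen[map_label(s, "T3")]

    def test_class_counts(self):
        assert TaskSpec.for_task("T1").n_classes == 2
        assert TaskSpec.for_task("T2").n_classes == 3
        assert TaskSpec.for_task("T3").n_classes == 5


class TestWorstSubtype:
    def test_examples(self):
        assert worst_subtype(["healthy", "nodular"]) == "nodular"
        assert worst_subtype(["healthy"]) == "healthy"
        assert worst_subtype(["superficial", "high", "medium"]) == "high"

    def test_order_invariant_and_idempotent(self):
        items = ["nodular", "healthy", "medium"]
        results = {worst_subtype(p) for p in itertools.permutations(items)}
        assert results == {"medium"}
        assert worst_subtype([worst_subtype(items)]) == "medium"

    def test_empty_and_unknown_rejected(self):
        with pytest.raises(ValueError):
            worst_subtype([])
        with pytest.raises(ValueError):
            worst_subtype(["healthy", "blah"])


class TestGroupedKfold:
    def test_even_partition(self):
        cases = [f"c{i}" for i in range(10)]
        fa = grouped_kfold(cases, 5, seed=0)
        sizes = sorted(len(fa.cases_in_fold(f)) for f in range(5))
        assert sizes == [2, 2, 2, 2, 2]

    def test_uneven_partition_sizes(self):
        fa = grouped_kfold([f"c{i}" for i in range(7)], 5, seed=1)
        sizes = sorted(len(fa.cases_in_fold(f)) for f in range(5))
        assert sizes == [1, 1, 1, 2, 2]

    def test_slides_of_one_case_share_a_fold(self):
        slide_cases = ["a", "a", "b", "c", "c", "c", "d", "e", "f"]
        fa = grouped_kfold(slide_cases, 3, seed=2)
        folds = fa.slide_folds(slide_cases)
        for case in set(slide_cases):
            per_case = folds[[i for i, c in enumerate(slide_cases) if c == case]]
            assert len(np.unique(per_case)) == 1

    def test_partition_is_exact_and_deterministic(self):
        cases = [f"c{i}" for i in range(23)]
        fa1 = grouped_kfold(cases, 5, seed=3)
        fa2 = grouped_kfold(cases, 5, seed=3)
        assert fa1.fold_of == fa2.fold_of
        all_assigned = [c for f in range(5) for c in fa1.cases_in_fold(f)]
        assert sorted(all_assigned) == sorted(cases)

    def test_fewer_cases_than_folds_rejected(self):
        with pytest.raises(ValueError):
            grouped_kfold(["a", "b"], 5)


class TestTrainConfig:
    def test_defaults_match_published_recipe(self):
        cfg = TrainConfig()
        assert cfg.batch_size == 4 and cfg.epochs == 100
        assert cfg.learning_rate == 1e-3 and cfg.weight_decay == 1e-5
        assert tuple(cfg.lr_decay_steps) == (40, 80) and cfg.lr_decay_factor == 0.1
        assert cfg.k_folds == 5

    def test_stepped_lr_schedule(self):
        cfg = TrainConfig()
        assert cfg.lr_at_epoch(0) == pytest.approx(1e-3)
        assert cfg.lr_at_epoch(39) == pytest.approx(1e-3)
        assert cfg.lr_at_epoch(40) == pytest.approx(1e-4)
        assert cfg.lr_at_epoch(80) == pytest.approx(1e-5)
        with pytest.raises(ValueError):
            TrainConfig(epochs=30, lr_decay_steps=(40, 80))


class TestTrainModel:
    def _graphs(self, seed=0):
        rng = np.random.default_rng(seed)
        graphs, labels = [], []
        for c in range(2):
            for _ in range(5):
                graphs.append(random_graph(rng, n=8, d=8, separable_shift=3.0 * c))
                labels.append(c)
        return graphs, labels

    def test_loss_decreases_and_training_is_deterministic(self):
        graphs, labels = self._graphs()
        mc = ModelConfig(n_classes=2, in_dim=8, embed_dim=8, mlp_dim=16,
                         n_attention_blocks=1, n_heads=2, pool_clusters=4)
        tc = TrainConfig(epochs=12, lr_decay_steps=(8, 10), seed=0)
        r1 = train_model(graphs, labels, mc, tc)
        r2 = train_model(graphs, labels, mc, tc)
        assert r1.loss_trace[-1] < r1.loss_trace[0]
        assert r1.loss_trace[-1] == pytest.approx(r2.loss_trace[-1], abs=1e-9)
        assert r1.lr_trace[8] == pytest.approx(1e-4)

    def test_single_class_fold_rejected(self):
        graphs, _ = self._graphs()
        mc = ModelConfig(n_classes=2, in_dim=8, embed_dim=8, mlp_dim=16,
                         n_attention_blocks=1, n_heads=2, pool_clusters=4)
        with pytest.raises(ValueError, match="single class"):
            train_model(graphs, [0] * len(graphs), mc,
                        TrainConfig(epochs=2, lr_decay_steps=()))


def _pred(cls, probs):
    return Prediction(slide_id="s", probabilities=np.asarray(probs, float),
                      predicted_class=cls)


class TestEnsemble:
    def test_strict_majority(self):
        preds = [_pred(v, np.eye(3)[v]) for v in (1, 1, 1, 0, 0)]
        assert ensemble_predict(preds) == 1

    def test_unanimity(self):
        preds = [_pred(2, np.eye(3)[2]) for _ in range(5)]
        assert ensemble_predict(preds) == 2

    def test_tie_broken_by_mean_probability(self):
        preds = [
            _pred(0, [0.50, 0.30, 0.20]),
            _pred(0, [0.40, 0.35, 0.25]),
            _pred(1, [0.30, 0.45, 0.25]),
            _pred(1, [0.35, 0.40, 0.25]),
            _pred(2, [0.20, 0.20, 0.60]),
        ]
        # classes 0 and 1 tie on votes; mean p(0)=0.35 > mean p(1)=0.34
        assert ensemble_predict(preds) == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ensemble_predict([])


class TestEvaluate:
    def test_hand_computed_binary_counts(self):
        # TP=9, FN=1 (class 1 = positive), TN=8, FP=2
        truths = [1] * 10 + [0] * 10
        preds = [1] * 9 + [0] + [0] * 8 + [1] * 2
        rep = evaluate(np.array(preds), truths, "T1")
        assert rep.accuracy == pytest.approx(0.85)
        assert rep.sensitivity[1] == pytest.approx(0.90)
        assert rep.specificity[1] == pytest.approx(0.80)
        assert rep.confusion.sum() == rep.n == 20

    def test_perfect_predictions(self):
        truths = [0, 1, 2, 0, 1, 2]
        rep = evaluate(np.array(truths), truths, "T2")
        assert rep.accuracy == 1.0
        assert all(s == 1.0 for s in rep.sensitivity)
        assert all(s == 1.0 for s in rep.specificity)

    def test_matches_bruteforce_confusion_oracle(self):
        rng = np.random.default_rng(0)
        truths = rng.integers(0, 5, size=200)
        preds = rng.integers(0, 5, size=200)
        rep = evaluate(preds, truths, "T3")
        cm = np.zeros((5, 5), int)
        for t, p in zip(truths, preds):
            cm[t, p] += 1
        assert np.array_equal(rep.confusion, cm)
        assert rep.accuracy == pytest.approx(np.trace(cm) / 200)
        for c in range(5):
            tp = cm[c, c]
            assert rep.sensitivity[c] == pytest.approx(tp / cm[c].sum())
            tn = cm.sum() - cm[c].sum() - cm[:, c].sum() + tp
            assert rep.specificity[c] == pytest.approx(
                tn / (tn + cm[:, c].sum() - tp))

    def test_absent_class_reported_as_missing(self):
        truths = [0, 0, 1, 1]   # class 2 never occurs
        rep = evaluate(np.array([0, 0, 1, 1]), truths, "T2")
        assert rep.sensitivity[2] is None

    def test_auc_from_probabilities(self):
        truths = [0, 0, 1, 1]
        preds = [_pred(t, [0.8 - 0.6 * t, 0.2 + 0.6 * t]) for t in truths]
        rep = evaluate(preds, truths, "T1")
        assert rep.auc[0] == 1.0 and rep.auc[1] == 1.0

    def test_mean_roc_vertical_averaging(self):
        truths = [np.array([0, 0, 1, 1]), np.array([0, 1, 0, 1])]
        probs = [np.array([[0.9, 0.1], [0.8, 0.2], [0.2, 0.8], [0.1, 0.9]])] * 2
        fpr, tpr = mean_roc(truths, probs, target_class=1)
        assert fpr[0] == 0.0 and fpr[-1] == 1.0
        assert tpr[-1] == 1.0
        assert np.all(np.diff(tpr) >= -1e-12)
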
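"""Continual-training orchestration: estimator contract, metrics
bookkeeping, task-specific batch-norm isolation, config runs, and the
capacity-saturation ordering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from metabnn.continual import (ContinualMetrics, evaluate_all,
                               hidden_weight_histogram, summarize_runs,
                               train_continual, train_interleaved)
from metabnn.estimator import MetaplasticBNNClassifier
from metabnn.tasks import SyntheticTaskSpec, generate_synthetic_tasks


def _clf(**kw):
    kw.setdefault("hidden_layer_sizes", (16,))
    kw.setdefault("learning_rate", 2e-2)
    kw.setdefault("batch_size", 16)
    kw.setdefault("n_epochs", 5)
    kw.setdefault("random_state", 0)
    return MetaplasticBNNClassifier(**kw)


class TestEstimatorContract:
    def test_clone_and_get_params_round_trip(self):
        clf = _clf(m=1.35, variant="hard_zero", hard_threshold=4.0)
        c2 = clone(clf)
        assert c2.get_params() == clf.get_params()

    def test_fit_predict_shapes_and_classes(self, small_tasks):
        x, y = small_tasks[0].train
        clf = _clf().fit(x, y)
        assert clf.predict(x).shape == y.shape
        np.testing.assert_array_equal(clf.classes_, np.unique(y))
        proba = clf.predict_proba(x)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)

    def test_untrained_network_predicts_at_chance(self, small_tasks):
        x, y = small_tasks[0].test
        clf = _clf()
        clf.partial_fit(*small_tasks[0].train, classes=np.unique(y), epochs=0)
        acc = clf.accuracy_percent(x, y)
        # 4 classes, 100 test points: binomial 99.9% interval around 25%
        assert 10.0 < acc < 42.0

    def test_deterministic_given_seed(self, small_tasks):
        x, y = small_tasks[0].train
        a = _clf().fit(x, y)
        b = _clf().fit(x, y)
        for ha, hb in zip(a.network_.hidden_weights(), b.network_.hidden_weights()):
            np.testing.assert_array_equal(ha, hb)

    def test_learning_improves_over_chance(self, small_tasks):
        x, y = small_tasks[0].train
        clf = _clf(n_epochs=15).fit(x, y)
        assert clf.accuracy_percent(*small_tasks[0].test) > 70.0


class TestMetricsBookkeeping:
    def test_row_count_is_epochs_times_tasks_seen(self, small_tasks):
        clf = _clf()
        metrics = train_continual(clf, small_tasks, epochs_per_task=3, seed=0)
        df = metrics.to_frame()
        # task k contributes epochs * (k+1) evaluation rows
        assert len(df) == sum(3 * (k + 1) for k in range(3))

    def test_accuracies_are_percentages(self, small_tasks):
        metrics = train_continual(_clf(), small_tasks, epochs_per_task=2, seed=0)
        acc = metrics.to_frame().accuracy
        assert acc.between(0, 100).all()

    def test_out_of_range_accuracy_rejected(self):
        with pytest.raises(ValueError):
            ContinualMetrics().log(0, 0, 0, 120.0)

    def test_final_vector_length(self, small_tasks):
        metrics = train_continual(_clf(), small_tasks, epochs_per_task=2, seed=0)
        assert len(metrics.final_accuracies) == len(small_tasks)

    def test_mean_over_learned_tasks(self, small_tasks):
        metrics = train_continual(_clf(), small_tasks, epochs_per_task=2, seed=0)
        expect = np.mean([metrics.accuracy(2, j) for j in range(3)])
        assert metrics.mean_over_learned(2) == pytest.approx(expect)

    def test_summarize_runs_mean_and_sd(self, small_tasks):
        runs = [train_continual(_clf(random_state=s), small_tasks,
                                epochs_per_task=2, seed=s) for s in (0, 1)]
        summary = summarize_runs(runs)
        a = runs[0].to_frame().set_index(["task_trained", "epoch", "eval_task"])
        b = runs[1].to_frame().set_index(["task_trained", "epoch", "eval_task"])
        row = summary.iloc[0]
        va, vb = a.accuracy.iloc[0], b.accuracy.iloc[0]
        assert row["mean"] == pytest.approx((va + vb) / 2)
        assert row["sd"] == pytest.approx(abs(va - vb) / 2)

    def test_unknown_method_rejected(self, small_tasks):
        with pytest.raises(ValueError, match="unknown method"):
            train_continual(_clf(), small_tasks, method="dreams")


class TestBatchNormSlots:
    def test_earlier_task_eval_unaffected_by_later_bn_updates(self, small_tasks):
        """Evaluating task 0 with its own slot restored yields the same
        accuracy whether or not other slots were updated afterwards."""
        clf = _clf(n_epochs=5)
        train_continual(clf, small_tasks, epochs_per_task=5, seed=0)
        before = evaluate_all(clf, small_tasks, 2).copy()
        # churn slot 1's statistics without touching weights
        clf.network_.use_bn_slot(1)
        x1, _ = small_tasks[1].train
        for _ in range(5):
            clf.network_.forward(x1[:32], training=True)
        after = evaluate_all(clf, small_tasks, 2)
        assert after[0] == before[0]
        assert after[2] == before[2]

    def test_evaluate_all_restores_active_slot(self, small_tasks):
        clf = _clf()
        train_continual(clf, small_tasks, epochs_per_task=2, seed=0)
        active = [bn.active for bn in clf.network_.all_batchnorms()]
        evaluate_all(clf, small_tasks, 2)
        assert [bn.active for bn in clf.network_.all_batchnorms()] == active


class TestHistogram:
    def test_mass_equals_parameter_count(self, small_tasks):
        clf = _clf().fit(*small_tasks[0].train)
        hists = hidden_weight_histogram(clf, bins=20)
        total = sum(counts.sum() for counts, _ in hists)
        assert total == clf.network_.n_parameters()

    def test_fresh_network_mass_near_zero(self, small_tasks):
        clf = _clf()
        clf.partial_fit(*small_tasks[0].train, classes=[0, 1, 2, 3], epochs=0)
        for counts, edges in hidden_weight_histogram(clf, bins=10, signed=False):
            assert edges[-1] <= 1.0  # init bound 1/sqrt(fan_in) < 1

    def test_consolidation_spreads_hidden_weights(self, small_tasks):
        clf = _clf(m=1.35, n_epochs=30).fit(*small_tasks[0].train)
        mags = np.concatenate([np.abs(h).ravel()
                               for h in clf.network_.hidden_weights()])
        assert np.mean(mags > 1.0) > 0.05


class TestInterleaved:
    def test_pooled_training_learns_all_tasks(self, small_tasks):
        clf = _clf(n_epochs=10)
        finals = train_interleaved(clf, small_tasks, epochs=10, seed=0)
        assert len(finals) == 3
        assert finals.mean() > 60.0


class TestCapacityOrdering:
    def test_saturated_network_fails_on_last_tasks_first(self):
        """Once most hidden weights are consolidated, early tasks keep their
        accuracy while the most recent tasks cannot be learned well."""
        spec = SyntheticTaskSpec(n_classes=4, n_features=24,
                                 n_train_per_class=60, n_test_per_class=25, seed=3)
        tasks = generate_synthetic_tasks(spec, 10)
        clf = MetaplasticBNNClassifier(hidden_layer_sizes=(24,), m=1.35,
                                       learning_rate=3e-2, batch_size=8,
                                       random_state=0)
        metrics = train_continual(clf, tasks, epochs_per_task=80, seed=0)
        finals = metrics.final_accuracies
        assert np.mean(finals[:3]) > np.mean(finals[-3:]) + 5.0


class TestConfigRuns:
    def _write(self, tmp_path, **overrides):
        import yaml
        cfg = {
            "experiment": "continual", "seed": 3,
            "output_dir": str(tmp_path / "out"),
            "network": {"hidden_layer_sizes": [16]},
            "optimizer": {"m": 1.0, "lr": 0.02},
            "tasks": {"n_tasks": 2,
                      "synthetic": {"n_classes": 4, "n_features": 24,
                                    "n_train_per_class": 40,
                                    "n_test_per_class": 10}},
            "training": {"epochs_per_task": 3, "batch_size": 16},
        }
        cfg.update(overrides)
        p = tmp_path / "cfg.yaml"
        p.write_text(yaml.safe_dump(cfg))
        return p

    def test_same_config_and_seed_reproduce_metrics(self, tmp_path):
        from metabnn.config import run_config
        p = self._write(tmp_path)
        run_config(p)
        first = (tmp_path / "out" / "metrics.csv").read_bytes()
        run_config(p)
        assert (tmp_path / "out" / "metrics.csv").read_bytes() == first

    def test_missing_key_named_in_error(self, tmp_path):
        from metabnn.config import ConfigError, run_config
        p = self._write(tmp_path)
        import yaml
        cfg = yaml.safe_load(p.read_text())
        del cfg["seed"]
        p.write_text(yaml.safe_dump(cfg))
        with pytest.raises(ConfigError, match="'seed'"):
            run_config(p)

    def test_dry_run_validates_without_artifacts(self, tmp_path):
        from metabnn.config import run_config
        p = self._write(tmp_path)
        out = run_config(p, dry_run=True)
        assert out["valid"] and not (tmp_path / "out").exists()

    def test_cli_dry_run(self, tmp_path):
        from click.testing import CliRunner
        from metabnn.cli import main
        p = self._write(tmp_path)
        res = CliRunner().invoke(main, ["train-continual", str(p), "--dry-run"])
        assert res.exit_code == 0, res.output
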
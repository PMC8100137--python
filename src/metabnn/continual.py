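"""Continual-training protocols: multitask, stream, and interleaved runs.

The central protocol constraint is that tasks are trained strictly in order
and earlier tasks' data is never revisited; consolidation must come from the
synapse model (metaplasticity) or from a baseline method (EWC variants,
learning-rate decay).  After every epoch all tasks seen so far are evaluated
with their own input transform and batch-norm slot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consolidation import (DEFAULT_LAMBDA_EWC, ImportanceMap, fisher_diag,
                            shuffle_importance, PathIntegralTracker)
from .estimator import MetaplasticBNNClassifier
from .network import binarize
from .optimizer import lr_decay_schedule
from .tasks import TaskSequence, interleaved_mixture, make_stream_shards

__all__ = [
    "ContinualMetrics",
    "train_continual",
    "train_stream",
    "train_interleaved",
    "evaluate_all",
    "hidden_weight_histogram",
    "count_flips",
    "summarize_runs",
]

METHODS = ("metaplasticity", "ewc", "random_ewc", "lr_decay", "si", "none")


@dataclass
class ContinualMetrics:
    """Per-epoch accuracy trajectories plus consolidation diagnostics.

    ``records`` rows: task_trained, epoch (within that task), eval_task,
    accuracy (percent).  ``final_accuracies[j]`` is task ``j``'s accuracy
    after the whole sequence; ``flip_counts[k]`` counts binary-weight sign
    flips during task ``k``; ``histograms[k]`` are per-layer signed
    hidden-weight histograms captured after task ``k``.
    """

    records: list = field(default_factory=list)
    final_accuracies: np.ndarray | None = None
    flip_counts: list = field(default_factory=list)
    histograms: list = field(default_factory=list)

    def log(self, task_trained: int, epoch: int, eval_task: int, acc: float):
        if not 0.0 <= acc <= 100.0:
            raise ValueError("accuracy must be a percentage in [0, 100]")
        self.records.append({"task_trained": task_trained, "epoch": epoch,
                             "eval_task": eval_task, "accuracy": acc})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def accuracy(self, task_trained: int, eval_task: int) -> float:
        """Accuracy on ``eval_task`` at the end of training ``task_trained``."""
        df = self.to_frame()
        sel = df[(df.task_trained == task_trained) & (df.eval_task == eval_task)]
        if sel.empty:
            raise KeyError((task_trained, eval_task))
        return float(sel.iloc[-1].accuracy)

    def mean_over_learned(self, task_trained: int) -> float:
        """Mean accuracy over tasks learned so far, at the end of a task."""
        accs = [self.accuracy(task_trained, j) for j in range(task_trained + 1)]
        return float(np.mean(accs))


def summarize_runs(runs: list) -> pd.DataFrame:
    """Mean and one standard deviation over repeated seeds.

    ``runs`` are :class:`ContinualMetrics` from identical protocols; returns
    a frame indexed by (task_trained, epoch, eval_task) with columns
    ``mean`` and ``sd`` (ddof=0 across runs).
    """
    if not runs:
        raise ValueError("no runs to summarize")
    frames = [r.to_frame().set_index(["task_trained", "epoch", "eval_task"])
              for r in runs]
    wide = pd.concat([f["accuracy"] for f in frames], axis=1)
    return pd.DataFrame({"mean": wide.mean(axis=1), "sd": wide.std(axis=1, ddof=0)})


def evaluate_all(clf: MetaplasticBNNClassifier, tasks: TaskSequence,
                 up_to_task: int) -> np.ndarray:
    """Accuracy (percent) on tasks ``0..up_to_task``, each with its own
    transform and batch-norm slot; the active slot is restored afterwards."""
    net = clf.network_
    bns = net.all_batchnorms()
    saved = [bn.active for bn in bns]
    out = np.empty(up_to_task + 1)
    for j in range(up_to_task + 1):
        task = tasks[j]
        net.use_bn_slot(task.bn_slot, create=True)
        x, y = task.test
        out[j] = clf.accuracy_percent(x, y)
    for bn, s in zip(bns, saved):
        bn.use_slot(s)
    return out


def count_flips(before: list, after: list) -> int:
    """Number of binary-weight sign changes between two hidden snapshots."""
    return int(sum(np.sum(binarize(a) != binarize(b))
                   for a, b in zip(before, after)))


def hidden_weight_histogram(clf_or_net, bins=50, signed=True):
    """Per-layer histogram of hidden weights (signed or magnitudes).

    Returns a list of ``(counts, edges)`` pairs; total counts equal the
    parameter count, so overlays across checkpoints are directly comparable.
    """
    net = getattr(clf_or_net, "network_", clf_or_net)
    out = []
    for h in net.hidden_weights():
        vals = h.ravel() if signed else np.abs(h).ravel()
        out.append(np.histogram(vals, bins=bins))
    return out


def _iter_batches(x, y, batch_size, rng):
    perm = rng.permutation(len(y))
    for i in range(0, len(perm), batch_size):
        idx = perm[i:i + batch_size]
        yield x[idx], y[idx]


def _fisher_for_task(clf, x, y, n_batches, lam, seed,
                     fisher_batch_size: int | None = None):
    """Empirical Fisher over up to ``n_batches`` minibatches of task data,
    cycling through reshuffles of the training set if it is smaller.

    The estimation batch defaults to the classifier's training batch size;
    larger batches suppress the ``var/batch`` sampling-noise floor that
    minibatch squared gradients add to unimportant synapses.
    """
    rng = np.random.default_rng(seed)
    y_idx = np.searchsorted(clf.classes_, y)
    bs = clf.batch_size if fisher_batch_size is None else int(fisher_batch_size)

    def batches():
        while True:
            yield from _iter_batches(x, y_idx, bs, rng)

    n = n_batches if bs < len(y_idx) else 1  # full batch: one pass is exact
    return fisher_diag(clf.network_, batches(), n_batches=n, lam=lam)


def train_continual(clf: MetaplasticBNNClassifier, tasks: TaskSequence,
                    method: str = "metaplasticity",
                    epochs_per_task: int | None = None,
                    lambda_ewc: float = DEFAULT_LAMBDA_EWC,
                    fisher_batches: int = 100,
                    seed: int = 0) -> ContinualMetrics:
    """Train ``clf`` on the task sequence strictly in order.

    ``method`` selects the consolidation mechanism:

    - ``"metaplasticity"`` / ``"none"``: the estimator's own ``m`` does the
      work (``"none"`` forces ``m = 0``);
    - ``"ewc"``: Fisher-diagonal elastic weight consolidation on binary
      weights, one anchored penalty per completed task, with ``m = 0``;
    - ``"random_ewc"``: as EWC but with importances shuffled across synapses;
    - ``"lr_decay"``: ``m = 0`` with the learning rate divided by ten per
      task;
    - ``"si"``: path-integral importance accumulated during each task, used
      like EWC maps.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if method != "metaplasticity":
        clf.set_params(m=0.0)
    metrics = ContinualMetrics()
    maps: list[ImportanceMap] = []
    epochs = clf.n_epochs if epochs_per_task is None else int(epochs_per_task)
    for k, task in enumerate(tasks):
        x, y = task.train
        lr = lr_decay_schedule(k, clf.learning_rate) if method == "lr_decay" else None
        before = None
        tracker = None
        for ep in range(epochs):
            if before is None:  # first epoch of the task: snapshot + tracker
                if k == 0 and not hasattr(clf, "network_"):
                    clf.partial_fit(x, y, classes=np.unique(y),
                                    bn_slot=task.bn_slot, epochs=0)
                before = [h.copy() for h in clf.network_.hidden_weights()]
                if method == "si":
                    tracker = PathIntegralTracker(clf.network_, on_binary=clf.binary,
                                                  lam=lambda_ewc)
            clf.partial_fit(
                x, y, bn_slot=task.bn_slot, epochs=1, lr=lr,
                ewc_maps=maps if method in ("ewc", "random_ewc", "si") else None,
                grad_hook=tracker.accumulate if tracker is not None else None)
            for j, acc in enumerate(evaluate_all(clf, tasks, k)):
                metrics.log(k, ep, j, acc)
        metrics.flip_counts.append(
            count_flips(before, clf.network_.hidden_weights()))
        metrics.histograms.append(hidden_weight_histogram(clf))
        if method in ("ewc", "random_ewc"):
            imap = _fisher_for_task(clf, x, y, fisher_batches, lambda_ewc,
                                    seed=seed * 997 + k)
            if method == "random_ewc":
                imap = shuffle_importance(imap, seed=seed * 991 + k)
            maps.append(imap)
        elif method == "si":
            maps.append(tracker.finalize())
    metrics.final_accuracies = evaluate_all(clf, tasks, len(tasks) - 1)
    return metrics


def train_stream(clf: MetaplasticBNNClassifier, dataset, n_shards: int,
                 shard_size: int, epochs_per_shard: int, seed: int = 0):
    """Stream learning: one task, trained shard by shard.

    The dataset is split into ``n_shards`` disjoint stratified subsets; each
    is trained for ``epochs_per_shard`` epochs and never revisited.
    Batch-norm state is common across shards (no task boundaries exist).
    Returns ``(test_accuracy_after_each_shard, shards)``.
    """
    shards = make_stream_shards(len(dataset.y_train), n_shards, shard_size,
                                seed=seed, labels=dataset.y_train)
    accs = []
    classes = np.unique(dataset.y_train)
    for s, idx in enumerate(shards):
        clf.partial_fit(dataset.x_train[idx], dataset.y_train[idx],
                        classes=classes, epochs=epochs_per_shard)
        accs.append(clf.accuracy_percent(dataset.x_test, dataset.y_test))
    return np.asarray(accs), shards


def train_interleaved(clf: MetaplasticBNNClassifier, tasks: TaskSequence,
                      epochs: int, seed: int = 0) -> np.ndarray:
    """Non-sequential baseline: all tasks' data pooled and shuffled each
    epoch; returns final per-task accuracies."""
    x, y, _ = interleaved_mixture(tasks, seed=seed)
    clf.partial_fit(x, y, classes=np.unique(y), epochs=epochs)
    return evaluate_all(clf, tasks, len(tasks) - 1)
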
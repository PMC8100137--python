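"""Consolidation baselines on the same binarized network.

Elastic weight consolidation (EWC) anchors each synapse to its value at the
end of a task with a quadratic penalty weighted by an importance estimate
(the diagonal of the Fisher information).  On a BNN both the importance and
the penalty are computed with the *binary* weight values, since the network's
response depends only on those; the penalty gradient reaches the hidden
weights through an identity straight-through pass on the binarization.

Also provided: the random-consolidation control (same importances, randomly
shuffled across synapses) and a path-integral importance in the style of
synaptic intelligence, usable on full-precision nets and as the documented
negative result on binary ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .network import Network, binarize

__all__ = [
    "ImportanceMap",
    "fisher_diag",
    "ewc_penalty",
    "ewc_grads",
    "shuffle_importance",
    "PathIntegralTracker",
]

DEFAULT_LAMBDA_EWC = 5e3


@dataclass
class ImportanceMap:
    """Per-synapse importances with the anchor binary weights of one task."""

    importances: list  # nonnegative arrays, one per weight layer
    anchors: list      # +/-1 arrays, one per weight layer
    lam: float = DEFAULT_LAMBDA_EWC

    def __post_init__(self):
        for f in self.importances:
            if np.any(f < 0):
                raise ValueError("importances must be nonnegative")
        for a in self.anchors:
            if not np.all(np.abs(a) == 1.0):
                raise ValueError("anchors must be +/-1")


def fisher_diag(net: Network, batches, n_batches: int = 100,
                lam: float = DEFAULT_LAMBDA_EWC) -> ImportanceMap:
    """Empirical Fisher diagonal: mean over batches of the squared
    log-likelihood gradient with respect to each binary weight.

    ``batches`` is an iterable of ``(x, y)`` pairs; up to ``n_batches`` are
    consumed.  Anchors are the current binary weights.
    """
    acc = [np.zeros_like(h) for h in net.hidden_weights()]
    used = 0
    for x, y in batches:
        _, wg, _ = net.loss_and_grad(x, y, training=False)
        for a, g in zip(acc, wg):
            a += g * g
        used += 1
        if used >= n_batches:
            break
    if used == 0:
        raise ValueError("fisher_diag: empty data iterator")
    importances = [a / used for a in acc]
    anchors = [binarize(h) for h in net.hidden_weights()]
    return ImportanceMap(importances=importances, anchors=anchors, lam=lam)


def ewc_penalty(net: Network, maps: list[ImportanceMap]) -> float:
    """Quadratic surrogate loss ``sum_tasks (lam/2) * sum_i F_i (W^b_i - W^b*_i)^2``.

    On binary weights each term is 0 (unflipped) or ``2 * lam * F_i``
    (flipped, since ``(+/-2)^2 = 4``).
    """
    if not maps:
        warnings.warn("ewc_penalty called with no importance maps; returning 0")
        return 0.0
    wb = [binarize(h) for h in net.hidden_weights()]
    total = 0.0
    for m in maps:
        for f, a, b in zip(m.importances, m.anchors, wb):
            d = b - a
            total += 0.5 * m.lam * float(np.sum(f * d * d))
    return total


def ewc_grads(net: Network, maps: list[ImportanceMap]) -> list[np.ndarray]:
    """Gradient of the EWC penalty wrt binary weights (identity STE to the
    hidden weights): ``sum_tasks lam * F_i * (W^b_i - W^b*_i)``."""
    grads = [np.zeros_like(h) for h in net.hidden_weights()]
    wb = [binarize(h) for h in net.hidden_weights()]
    for m in maps:
        for g, f, a, b in zip(grads, m.importances, m.anchors, wb):
            g += m.lam * f * (b - a)
    return grads


def shuffle_importance(imap: ImportanceMap, seed: int) -> ImportanceMap:
    """Random-consolidation control: permute the importance factors uniformly
    across all synapses (multiset preserved exactly); anchors unchanged."""
    rng = np.random.default_rng(seed)
    flat = np.concatenate([f.ravel() for f in imap.importances])
    perm = rng.permutation(flat.size)
    shuffled = flat[perm]
    out = []
    k = 0
    for f in imap.importances:
        out.append(shuffled[k:k + f.size].reshape(f.shape).copy())
        k += f.size
    return ImportanceMap(importances=out,
                         anchors=[a.copy() for a in imap.anchors],
                         lam=imap.lam)


class PathIntegralTracker:
    """Synaptic-intelligence-style importance: running sum of
    ``-grad * delta_param`` per synapse over a task, normalized at the end by
    the squared total displacement plus a damping term.

    ``on_binary=True`` accumulates the path integral with binary-weight
    displacements (in ``{0, +/-2}``), which concentrates all importance on
    flipped synapses — the behaviour that makes the method ill-suited to
    BNNs.  On full-precision nets use ``on_binary=False``.
    """

    def __init__(self, net: Network, on_binary: bool = False, damping: float = 0.1,
                 lam: float = DEFAULT_LAMBDA_EWC):
        self.net = net
        self.on_binary = on_binary
        self.damping = float(damping)
        self.lam = lam
        self._omega = [np.zeros_like(h) for h in net.hidden_weights()]
        self._prev = self._snapshot()
        self._start = self._snapshot()

    def _snapshot(self):
        if self.on_binary:
            return [binarize(h) for h in self.net.hidden_weights()]
        return [h.copy() for h in self.net.hidden_weights()]

    def accumulate(self, weight_grads) -> None:
        """Call after each optimizer step with the gradients used for it."""
        cur = self._snapshot()
        for om, g, new, old in zip(self._omega, weight_grads, cur, self._prev):
            om -= g * (new - old)
        self._prev = cur

    def finalize(self) -> ImportanceMap:
        cur = self._snapshot()
        importances = []
        for om, new, start in zip(self._omega, cur, self._start):
            disp = new - start
            importances.append(np.maximum(om, 0.0) / (disp * disp + self.damping))
        anchors = [binarize(h) for h in self.net.hidden_weights()]
        return ImportanceMap(importances=importances, anchors=anchors, lam=self.lam)
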
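"""Metaplastic Adam: consolidation through attenuated hidden-weight updates.

The rule modifies standard BNN training in a single place.  Adam prescribes a
composite update ``U_W`` for each hidden weight.  Where that update would push
the hidden weight back toward zero — i.e. where ``U_W * W^b > 0`` with
``W^b = sign(W^h)`` — it is multiplied by the metaplasticity function

    f_meta(m, W^h) = 1 - tanh^2(m * W^h)

evaluated at the pre-update hidden value.  Updates that grow ``|W^h|`` pass
unattenuated, so hidden weights of consistently reinforced synapses drift away
from zero and become exponentially harder to flip back: the hidden weight acts
as a per-synapse consolidation (metaplasticity) variable.  ``m >= 0`` is the
only hyper-parameter introduced; ``m = 0`` recovers plain Adam-BNN training
exactly.  Batch-norm parameters are real-valued and always updated
unattenuated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .network import Network, binarize

__all__ = [
    "f_meta",
    "f_meta_hard_zero",
    "default_hard_threshold",
    "lr_decay_schedule",
    "MetaplasticityConfig",
    "MetaplasticAdam",
]


def f_meta(m: float, w) -> np.ndarray:
    """Metaplastic attenuation ``1 - tanh^2(m * w)`` (= ``sech^2(m w)``).

    Value in ``(0, 1]``: equals 1 at ``m = 0`` or ``w = 0``, is even in ``w``
    with zero slope at the origin, and decays exponentially to 0 as
    ``|w| -> inf``.
    """
    if m < 0:
        raise ValueError(f"metaplasticity parameter m must be >= 0, got {m}")
    # sech^2 computed from exponentials: 1 - tanh^2 underflows to exactly 0
    # once |m w| exceeds ~19, while this form stays positive to ~350
    a = np.abs(m * np.asarray(w, dtype=float))
    e = np.exp(-2.0 * a)
    # rounding can land one ulp above 1 for tiny arguments; clamp to range
    return np.minimum(4.0 * e / (1.0 + e) ** 2, 1.0)


def default_hard_threshold(m: float, floor: float = 1e-3) -> float:
    """Hidden-weight magnitude where the smooth f_meta drops below ``floor``.

    Used as the default cut-off of the hard-zero variant so that it only
    departs from the smooth rule in the already-saturated tail.
    """
    if m <= 0:
        return math.inf
    return math.atanh(math.sqrt(1.0 - floor)) / m


def f_meta_hard_zero(m: float, w, threshold: float) -> np.ndarray:
    """Hard-zero variant: smooth f_meta below ``|w| < threshold``, exactly 0
    at and beyond it, making consolidation definitive past the cut-off."""
    if threshold is None:
        raise ValueError("hard-zero variant requires a threshold")
    if not threshold > 0:
        raise ValueError("hard-zero threshold must be positive")
    w = np.asarray(w, dtype=float)
    out = f_meta(m, w)
    return np.where(np.abs(w) >= threshold, 0.0, out)


def lr_decay_schedule(task_index: int, base_lr: float) -> float:
    """Task-dependent learning-rate decay control: divide by ten per task."""
    if task_index < 0:
        raise ValueError("task_index must be >= 0")
    return base_lr * 10.0 ** (-task_index)


@dataclass
class MetaplasticityConfig:
    """Consolidation settings: strength ``m``, smooth or hard-zero variant."""

    m: float = 0.0
    variant: str = "smooth"  # "smooth" | "hard_zero"
    hard_threshold: float | None = None  # None -> default_hard_threshold(m)

    def __post_init__(self):
        if self.m < 0:
            raise ValueError("m must be >= 0")
        if self.variant not in ("smooth", "hard_zero"):
            raise ValueError(f"unknown f_meta variant {self.variant!r}")

    def attenuation(self, w: np.ndarray) -> np.ndarray:
        if self.variant == "smooth":
            return f_meta(self.m, w)
        thr = self.hard_threshold
        if thr is None:
            thr = default_hard_threshold(self.m)
        return f_meta_hard_zero(self.m, w, thr)


class MetaplasticAdam:
    """Adam with metaplastic attenuation of sign-opposing weight updates.

    Parameters
    ----------
    net : Network
        The model whose hidden weights and active batch-norm slot are updated
        in place.
    m, variant, hard_threshold :
        See :class:`MetaplasticityConfig`.
    lr, betas, eps :
        Adam hyper-parameters (defaults 1e-3, (0.9, 0.999), 1e-8).

    Notes
    -----
    The attenuation multiplies the full Adam composite update, not the raw
    gradient, and the branch condition compares the update's direction with
    the *binary* sign ``W^b``; strict inequality, so a zero update is a no-op
    through the unattenuated branch.
    """

    def __init__(self, net: Network, m: float = 0.0, variant: str = "smooth",
                 hard_threshold: float | None = None, lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.net = net
        self.cfg = MetaplasticityConfig(m=m, variant=variant, hard_threshold=hard_threshold)
        self.lr = float(lr)
        self.beta1, self.beta2 = float(betas[0]), float(betas[1])
        self.eps = float(eps)
        self.t = 0
        self.m1_w = [np.zeros_like(h) for h in net.hidden_weights()]
        self.m2_w = [np.zeros_like(h) for h in net.hidden_weights()]
        self._bn_moments = {}

    # -- Adam plumbing ------------------------------------------------------

    def _adam_update(self, g, m1, m2):
        m1 *= self.beta1
        m1 += (1 - self.beta1) * g
        m2 *= self.beta2
        m2 += (1 - self.beta2) * g * g
        mhat = m1 / (1 - self.beta1 ** self.t)
        vhat = m2 / (1 - self.beta2 ** self.t)
        return mhat / (np.sqrt(vhat) + self.eps)

    def _bn_state(self, bn_index, slot, which, shape):
        key = (bn_index, slot, which)
        if key not in self._bn_moments:
            self._bn_moments[key] = (np.zeros(shape), np.zeros(shape))
        return self._bn_moments[key]

    # -- the update rule ----------------------------------------------------

    def step(self, weight_grads, bn_grads, lr: float | None = None) -> None:
        """Apply one optimization step in place.

        ``weight_grads`` aligns with ``net.weight_layers()`` (gradients wrt
        binary weights), ``bn_grads`` with ``net.all_batchnorms()`` as
        ``(dgamma, dbeta)`` for the active slot.
        """
        if lr is None:
            lr = self.lr
        self.t += 1
        layers = self.net.weight_layers()
        if len(weight_grads) != len(layers):
            raise ValueError("weight_grads does not match the network's layers")
        for lyr, g, m1, m2 in zip(layers, weight_grads, self.m1_w, self.m2_w):
            if g.shape != lyr.hidden.shape:
                raise ValueError(
                    f"gradient shape {g.shape} != weight shape {lyr.hidden.shape}")
            u = self._adam_update(g, m1, m2)
            wb = binarize(lyr.hidden)
            toward_zero = u * wb > 0.0  # strict: the update opposes the sign
            atten = np.where(toward_zero, self.cfg.attenuation(lyr.hidden), 1.0)
            lyr.hidden -= lr * u * atten
        bns = self.net.all_batchnorms()
        for i, (bn, (dg, db)) in enumerate(zip(bns, bn_grads)):
            st = bn.state
            for which, grad, param in (("gamma", dg, st["gamma"]),
                                       ("beta", db, st["beta"])):
                m1, m2 = self._bn_state(i, bn.active, which, grad.shape)
                u = self._adam_update(grad, m1, m2)
                param -= lr * u
        # refresh binary read-out happens implicitly: layers binarize on use

    # -- serialization ------------------------------------------------------

    def state_dict(self) -> dict:
        out = {"t": self.t, "lr": self.lr, "beta1": self.beta1,
               "beta2": self.beta2, "eps": self.eps,
               "m": self.cfg.m, "variant": self.cfg.variant}
        for i, (a, b) in enumerate(zip(self.m1_w, self.m2_w)):
            out[f"m1_w{i}"] = a
            out[f"m2_w{i}"] = b
        return out

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        for i in range(len(self.m1_w)):
            self.m1_w[i][...] = state[f"m1_w{i}"]
            self.m2_w[i][...] = state[f"m2_w{i}"]
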
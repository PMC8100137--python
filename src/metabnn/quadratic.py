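"""The quadratic binary task: a tractable model of BNN hidden-weight dynamics.

The task is to minimize the convex quadratic ``L(W) = 1/2 (W - W*)^T H (W - W*)``
(``H`` symmetric positive definite, ``W*`` the real-valued optimum) while the
gradient is evaluated only at the binary point ``sign(W^h)``:

    W^h_{t+1} = W^h_t - eta * H @ (sign(W^h_t) - W*)

exactly as BNN training evaluates loss gradients at the binary weights.  With
a diagonal curvature, any coordinate with ``|W*_i| > 1`` has a hidden weight
that diverges linearly with asymptotic slope ``eta * lambda_i * (|W*_i| - 1)
* sign(W*_i)``, and the loss increase from flipping that coordinate's sign
approaches ``2 lambda_i + 2 |slope_i| / eta`` — i.e. large hidden weights mark
binary weights whose flip is costly.  This module simulates the scheme,
estimates divergence slopes, computes exact flip-loss deltas, generates
random SPD curvatures by the subgroup algorithm, and performs the binned
flip-loss analysis (for the task itself and for trained BNNs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .network import Network, binarize

__all__ = [
    "QuadraticBinaryTask",
    "DivergenceSummary",
    "random_spd",
    "run_trajectory",
    "flip_loss_delta",
    "binned_flip_analysis",
    "binned_flip_analysis_bnn",
]


@dataclass
class QuadraticBinaryTask:
    """State of one optimization run of the quadratic binary task."""

    H: np.ndarray
    W_star: np.ndarray
    eta: float = 0.1
    W_h: np.ndarray | None = None

    def __post_init__(self):
        self.H = np.asarray(self.H, dtype=float)
        self.W_star = np.asarray(self.W_star, dtype=float)
        d = self.W_star.size
        if self.H.shape != (d, d):
            raise ValueError("H and W_star dimensions disagree")
        if not np.allclose(self.H, self.H.T, atol=1e-8):
            raise ValueError("H must be symmetric")
        eigs = np.linalg.eigvalsh(self.H)
        if eigs.min() <= 0:
            raise ValueError("H must be positive definite")
        self._max_eig = float(eigs.max())
        if self.W_h is None:
            self.W_h = np.zeros(d) + 1e-12  # sign(0)=+1 convention made explicit
        self.W_h = np.asarray(self.W_h, dtype=float).copy()

    @property
    def d(self) -> int:
        return self.W_star.size

    def binary(self) -> np.ndarray:
        return binarize(self.W_h)

    def loss(self, W_b: np.ndarray | None = None) -> float:
        """``1/2 (W^b - W*)^T H (W^b - W*)`` evaluated at the binary read-out."""
        if W_b is None:
            W_b = self.binary()
        W_b = np.asarray(W_b, dtype=float)
        if W_b.shape != self.W_star.shape:
            raise ValueError("dimension mismatch")
        d = W_b - self.W_star
        return 0.5 * float(d @ self.H @ d)

    def step(self) -> np.ndarray:
        """One update ``W^h <- W^h - eta H (sign(W^h) - W*)``; returns W^h."""
        self.W_h -= self.eta * self.H @ (self.binary() - self.W_star)
        return self.W_h


@dataclass
class DivergenceSummary:
    """Per-coordinate asymptotic slope of the hidden weight (units/step)."""

    slopes: np.ndarray
    diverging: np.ndarray  # bool mask: |slope| > tolerance
    tolerance: float


def run_trajectory(task: QuadraticBinaryTask, T: int, record_every: int = 1):
    """Advance ``T`` steps, recording every ``record_every``-th state.

    Slopes are least-squares fits over the last half of the recorded
    trajectory; a coordinate is flagged diverging when ``|slope|`` exceeds
    ``1e-3 * eta * max_eigenvalue(H)``.

    Returns ``(times, states, DivergenceSummary)`` where ``states`` has shape
    ``(n_records, d)``.
    """
    if T < 2:
        raise ValueError("T must be >= 2 for a slope fit")
    times = []
    states = []
    for t in range(1, T + 1):
        task.step()
        if t % record_every == 0:
            times.append(t)
            states.append(task.W_h.copy())
    times = np.asarray(times, dtype=float)
    states = np.asarray(states)
    half = len(times) // 2
    tt, ss = times[half:], states[half:]
    if len(tt) < 2:
        raise ValueError("trajectory too short for a slope fit; lower record_every")
    A = np.vstack([tt, np.ones_like(tt)]).T
    coef, *_ = np.linalg.lstsq(A, ss, rcond=None)
    slopes = coef[0]
    tol = 1e-3 * task.eta * task._max_eig
    return times, states, DivergenceSummary(
        slopes=slopes, diverging=np.abs(slopes) > tol, tolerance=tol)


def flip_loss_delta(task: QuadraticBinaryTask, i: int) -> float:
    """Exact loss change from flipping the sign of binary coordinate ``i``.

    For state ``s`` and residual ``d = s - W*``:
    ``Delta_i L = 2 H_ii - 2 s_i (H d)_i``; with diagonal ``H`` this reduces
    to ``2 lambda_i s_i W*_i``.
    """
    if not 0 <= i < task.d:
        raise IndexError(f"coordinate {i} out of range for d={task.d}")
    s = task.binary()
    d = s - task.W_star
    return 2.0 * float(task.H[i, i]) - 2.0 * float(s[i] * (task.H @ d)[i])


def random_spd(d: int, eigenvalue_spec: dict | None = None, seed: int = 0):
    """Random symmetric positive-definite matrix ``H = R^T D R``.

    ``D`` holds eigenvalues drawn from ``eigenvalue_spec``
    (``{"dist": "uniform", "low", "high"}`` or ``{"dist": "normal", "mean",
    "sd"}``); non-positive draws are resampled.  ``R`` is a Haar-like random
    rotation from the subgroup algorithm: start from a random 2-D rotation
    and lift the dimension one at a time with the reflection
    ``R_{n+1} = (I - 2 x x^T) @ Rhat_n`` where ``x = (e1 - v) / ||e1 - v||``
    and ``v`` is uniform on the sphere.

    Returns ``(H, eigenvalues, R)``.
    """
    if d < 2:
        raise ValueError("random_spd requires d >= 2")
    spec = dict(eigenvalue_spec or {"dist": "uniform", "low": 0.5, "high": 2.0})
    rng = np.random.default_rng(seed)

    def draw(n):
        if spec["dist"] == "uniform":
            return rng.uniform(spec["low"], spec["high"], size=n)
        if spec["dist"] == "normal":
            return rng.normal(spec["mean"], spec["sd"], size=n)
        raise ValueError(f"unknown eigenvalue distribution {spec['dist']!r}")

    eigs = draw(d)
    for _ in range(1000):
        bad = eigs <= 0
        if not bad.any():
            break
        eigs[bad] = draw(int(bad.sum()))
    else:
        raise ValueError("eigenvalue spec keeps producing non-positive values")

    theta = rng.uniform(0.0, 2.0 * np.pi)
    R = np.array([[np.cos(theta), -np.sin(theta)],
                  [np.sin(theta), np.cos(theta)]])
    for n in range(2, d):
        v = rng.normal(size=n + 1)
        v /= np.linalg.norm(v)
        e1 = np.zeros(n + 1)
        e1[0] = 1.0
        diff = e1 - v
        norm = np.linalg.norm(diff)
        if norm < 1e-12:  # v == e1: reflection degenerates to identity lift
            x = None
        else:
            x = diff / norm
        Rhat = np.zeros((n + 1, n + 1))
        Rhat[0, 0] = 1.0
        Rhat[1:, 1:] = R
        R = Rhat if x is None else (np.eye(n + 1) - 2.0 * np.outer(x, x)) @ Rhat
    H = R.T @ np.diag(eigs) @ R
    H = 0.5 * (H + H.T)  # exact symmetry against rounding
    return H, eigs, R


# ---------------------------------------------------------------------------
# Binned flip-loss analysis


def _bin_stats(norm_w, deltas, bins):
    edges = np.linspace(0.0, 1.0, bins + 1)
    idx = np.clip(np.digitize(norm_w, edges) - 1, 0, bins - 1)
    rows = []
    for b in range(bins):
        sel = idx == b
        if not sel.any():
            rows.append({"bin": b, "lo": edges[b], "hi": edges[b + 1],
                         "n": 0, "mean": np.nan, "sd": np.nan})
            continue
        rows.append({"bin": b, "lo": edges[b], "hi": edges[b + 1],
                     "n": int(sel.sum()),
                     "mean": float(np.mean(deltas[sel])),
                     "sd": float(np.std(deltas[sel]))})
    return rows


def binned_flip_analysis(task: QuadraticBinaryTask, bins: int = 10):
    """Per-bin mean +/- sd of the single-flip loss increase, with hidden
    weights binned by ``|W^h| / max|W^h|``.

    Returns ``(rows, spearman_rho)`` where ``rho`` is the Spearman rank
    correlation between occupied-bin index and mean loss increase.  Empty
    bins are reported with ``n = 0`` and NaN statistics.
    """
    w = np.abs(task.W_h)
    norm_w = w / w.max()
    deltas = np.array([flip_loss_delta(task, i) for i in range(task.d)])
    rows = _bin_stats(norm_w, deltas, bins)
    return rows, _occupied_rho(rows)


def binned_flip_analysis_bnn(net: Network, x: np.ndarray, y: np.ndarray,
                             layer: int, bins: int = 10, flips_per_bin: int = 100,
                             realizations: int = 100, seed: int = 0):
    """Binned sign-switch analysis on a trained BNN layer.

    Within each bin of normalized ``|W^h|`` (normalizer: the layer's max),
    ``flips_per_bin`` hidden weights are sign-flipped simultaneously, the
    cost variation on ``(x, y)`` is measured, normalized per flipped weight,
    and averaged over ``realizations`` draws of the flipped set.

    Returns ``(rows, spearman_rho)`` as in :func:`binned_flip_analysis`.
    """
    rng = np.random.default_rng(seed)
    lyr = net.weight_layers()[layer]
    hidden = lyr.hidden
    w = np.abs(hidden).ravel()
    norm_w = w / w.max()
    edges = np.linspace(0.0, 1.0, bins + 1)
    idx = np.clip(np.digitize(norm_w, edges) - 1, 0, bins - 1)

    def mean_loss():
        scores = net.predict_scores(x)
        z = scores - scores.max(axis=1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
        return -float(np.mean(logp[np.arange(len(y)), y]))

    base = mean_loss()
    rows = []
    for b in range(bins):
        members = np.flatnonzero(idx == b)
        if members.size == 0:
            rows.append({"bin": b, "lo": edges[b], "hi": edges[b + 1],
                         "n": 0, "mean": np.nan, "sd": np.nan})
            continue
        k = min(flips_per_bin, members.size)
        vals = []
        for _ in range(realizations):
            if k == 0:
                vals.append(0.0)
                continue
            pick = rng.choice(members, size=k, replace=False)
            flat = hidden.ravel()
            flat[pick] *= -1.0
            vals.append((mean_loss() - base) / k)
            flat[pick] *= -1.0  # restore exactly
        rows.append({"bin": b, "lo": edges[b], "hi": edges[b + 1],
                     "n": int(members.size),
                     "mean": float(np.mean(vals)), "sd": float(np.std(vals))})
    return rows, _occupied_rho(rows)


def _occupied_rho(rows) -> float:
    occ = [r for r in rows if r["n"] > 0]
    means = [r["mean"] for r in occ]
    if len(occ) < 3 or len(set(means)) < 2:
        return float("nan")
    return float(stats.spearmanr([r["bin"] for r in occ], means).statistic)
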
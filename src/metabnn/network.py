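"""Binarized network core: layers, straight-through gradients, batch norm.

A binarized neural network (BNN) keeps, for every synapse, a real-valued
*hidden* weight ``W^h`` that accumulates training updates, and uses only its
sign ``W^b = sign(W^h)`` in the forward and backward passes.  Hidden
activations are likewise binarized through ``sign``, with the
straight-through estimator (STE) providing a surrogate gradient.  A
full-precision control network shares the same code path but uses the real
weights directly and a ``tanh`` activation.

Hidden weights are deliberately *not* clipped to ``[-1, 1]``: their unbounded
growth is the consolidation signal the metaplastic optimizer relies on.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

__all__ = [
    "binarize",
    "NetworkSpec",
    "mlp_spec",
    "vgg7_spec",
    "Network",
    "build_network",
    "save_checkpoint",
    "load_checkpoint",
]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


def binarize(hidden: np.ndarray) -> np.ndarray:
    """Elementwise sign with the tie convention ``sign(0) = +1``.

    Parameters
    ----------
    hidden : ndarray
        Real-valued hidden weights; must be finite.

    Returns
    -------
    ndarray of the same shape with entries in ``{+1.0, -1.0}``.
    """
    hidden = np.asarray(hidden)
    if not np.all(np.isfinite(hidden)):
        bad = int(np.sum(~np.isfinite(hidden)))
        raise ValueError(f"binarize: {bad} non-finite hidden weight(s)")
    return np.where(hidden >= 0.0, 1.0, -1.0)


# ---------------------------------------------------------------------------
# Specs


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description.

    ``kind`` is ``"mlp"`` (``layer_sizes`` = input, hidden..., output) or
    ``"conv"`` (``conv_channels`` 3x3 conv stack with 2x2 max-pool after every
    second conv, followed by ``dense_sizes`` fully connected layers).
    ``binary=False`` selects the full-precision control network, which uses
    real weights and (by default) a ``tanh`` hidden activation instead of
    ``sign``.  ``dropout`` gives per-dense-layer drop probabilities (applied
    to that layer's input); a scalar broadcasts over the hidden dense layers.
    """

    kind: str = "mlp"
    layer_sizes: tuple = ()
    conv_channels: tuple = ()
    dense_sizes: tuple = ()
    input_shape: tuple = ()
    binary: bool = True
    activation: str = "auto"  # "sign" | "tanh" | "auto"
    batch_norm: bool = True
    dropout: tuple = ()

    def resolved_activation(self) -> str:
        if self.activation != "auto":
            return self.activation
        return "sign" if self.binary else "tanh"

    def validate(self) -> None:
        if self.kind not in ("mlp", "conv"):
            raise ValueError(f"unknown network kind {self.kind!r}")
        if self.kind == "mlp" and len(self.layer_sizes) < 2:
            raise ValueError("mlp spec needs at least input and output sizes")
        if self.kind == "conv":
            if len(self.input_shape) != 3:
                raise ValueError("conv spec needs input_shape (C, H, W)")
            if not self.conv_channels or not self.dense_sizes:
                raise ValueError("conv spec needs conv_channels and dense_sizes")
        act = self.resolved_activation()
        if act not in ("sign", "tanh"):
            raise ValueError(f"unknown activation {act!r}")
        if self.binary and act != "sign":
            raise ValueError("binarized layers use the sign activation")


def mlp_spec(layer_sizes, binary=True, batch_norm=True, dropout=0.0) -> NetworkSpec:
    """Fully connected spec, e.g. ``mlp_spec((784, 4096, 4096, 10))``."""
    sizes = tuple(int(s) for s in layer_sizes)
    n_hidden = len(sizes) - 2
    if np.isscalar(dropout):
        drop = (float(dropout),) * n_hidden + (0.0,)
    else:
        drop = tuple(float(p) for p in dropout)
    if len(drop) != len(sizes) - 1:
        raise ValueError("dropout length must match the number of weight layers")
    return NetworkSpec(kind="mlp", layer_sizes=sizes, binary=bool(binary),
                       batch_norm=bool(batch_norm), dropout=drop)


def vgg7_spec(input_shape=(3, 32, 32), n_classes=10, binary=True) -> NetworkSpec:
    """Binary VGG-7: six 3x3 conv layers of 128-128-256-256-512-512 filters
    (2x2 max-pool after every second conv) and three dense layers with two
    2048-unit hidden layers, dropout 0.5 on the inputs of the last two dense
    layers."""
    return NetworkSpec(
        kind="conv",
        conv_channels=(128, 128, 256, 256, 512, 512),
        dense_sizes=(2048, 2048, int(n_classes)),
        input_shape=tuple(int(s) for s in input_shape),
        binary=bool(binary),
        dropout=(0.0, 0.5, 0.5),
    )


# ---------------------------------------------------------------------------
# Layers


class BatchNorm:
    """Per-neuron batch normalization with task-slot support.

    Each slot holds a complete state (scale ``gamma``, shift ``beta``, running
    mean/variance); restoring a task's slot restores its normalization
    exactly, which isolates weight consolidation effects across tasks.
    """

    def __init__(self, n: int):
        self.n = n
        self.slots = {0: self._fresh_state()}
        self.active = 0
        self._cache = None

    def _fresh_state(self):
        return {
            "gamma": np.ones(self.n),
            "beta": np.zeros(self.n),
            "running_mean": np.zeros(self.n),
            "running_var": np.ones(self.n),
        }

    def use_slot(self, slot: int, create: bool = True) -> None:
        if slot not in self.slots:
            if not create:
                raise KeyError(f"batch-norm slot {slot} does not exist")
            self.slots[slot] = self._fresh_state()
        self.active = slot

    @property
    def state(self):
        return self.slots[self.active]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        st = self.state
        if training:
            if x.shape[0] < 2:
                raise ValueError("batch norm in training mode needs batch size >= 2")
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            st["running_mean"] = (1 - _BN_MOMENTUM) * st["running_mean"] + _BN_MOMENTUM * mean
            st["running_var"] = (1 - _BN_MOMENTUM) * st["running_var"] + _BN_MOMENTUM * var
        else:
            mean = st["running_mean"]
            var = st["running_var"]
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (x - mean) * inv_std
        self._cache = (xhat, inv_std)
        return st["gamma"] * xhat + st["beta"]

    def backward(self, dy: np.ndarray, training: bool):
        xhat, inv_std = self._cache
        st = self.state
        dgamma = np.sum(dy * xhat, axis=0)
        dbeta = np.sum(dy, axis=0)
        if training:
            n = dy.shape[0]
            dxhat = dy * st["gamma"]
            dx = inv_std / n * (
                n * dxhat - np.sum(dxhat, axis=0) - xhat * np.sum(dxhat * xhat, axis=0)
            )
        else:
            dx = dy * st["gamma"] * inv_std
        return dx, dgamma, dbeta


class DenseLayer:
    """Linear layer whose effective weight is ``sign(W^h)`` when binary."""

    def __init__(self, fan_in: int, fan_out: int, binary: bool, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(fan_in)
        self.hidden = rng.uniform(-bound, bound, size=(fan_in, fan_out))
        self.binary = binary
        self.fan_in, self.fan_out = fan_in, fan_out
        self._x = None

    def effective_weight(self) -> np.ndarray:
        return binarize(self.hidden) if self.binary else self.hidden

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.effective_weight()

    def backward(self, dy: np.ndarray):
        w = self.effective_weight()
        dw = self._x.T @ dy  # gradient wrt the *effective* (binary) weight
        dx = dy @ w.T
        return dx, dw


class ConvLayer:
    """3x3 same-padding convolution (stride 1) with binary or real weights."""

    def __init__(self, c_in: int, c_out: int, binary: bool, rng: np.random.Generator):
        fan_in = c_in * 9
        bound = 1.0 / np.sqrt(fan_in)
        self.hidden = rng.uniform(-bound, bound, size=(c_out, c_in, 3, 3))
        self.binary = binary
        self._cols = None
        self._xshape = None

    def effective_weight(self) -> np.ndarray:
        return binarize(self.hidden) if self.binary else self.hidden

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)
        self._cols, self._xshape = cols, x.shape
        wmat = self.effective_weight().reshape(-1, c * 9)
        out = cols @ wmat.T
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray):
        n, c, h, w = self._xshape
        c_out = dy.shape[1]
        dy_mat = dy.transpose(0, 2, 3, 1).reshape(n * h * w, c_out)
        wmat = self.effective_weight().reshape(c_out, c * 9)
        dw = (dy_mat.T @ self._cols).reshape(self.hidden.shape)
        dcols = dy_mat @ wmat
        dxp = np.zeros((n, c, h + 2, w + 2))
        dcols = dcols.reshape(n, h, w, c, 3, 3)
        for di in range(3):
            for dj in range(3):
                dxp[:, :, di:di + h, dj:dj + w] += dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        return dxp[:, :, 1:-1, 1:-1], dw


class MaxPool2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        x4 = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = x4.max(axis=(3, 5))
        self._mask = x4 == out[:, :, :, None, :, None]
        self._shape = x.shape
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        # ties split the upstream gradient equally (valid subgradient)
        mask = self._mask
        counts = mask.sum(axis=(3, 5), keepdims=True)
        dy6 = dy[:, :, :, None, :, None] * (mask / counts)
        return dy6.reshape(self._shape)


class _SignAct:
    def forward(self, a):
        self._a = a
        return binarize(a)

    def backward(self, dy):
        # straight-through estimator: hard-tanh window |a| <= 1
        return dy * (np.abs(self._a) <= 1.0)


class _TanhAct:
    def forward(self, a):
        self._t = np.tanh(a)
        return self._t

    def backward(self, dy):
        return dy * (1.0 - self._t ** 2)


# ---------------------------------------------------------------------------
# Network


class Network:
    """A feed-forward (binary or full-precision) classifier network.

    The hidden layers apply ``linear -> batch norm -> activation`` and the
    output layer ``linear -> batch norm`` producing real-valued class scores.
    Inputs are expected pre-scaled to ``[-1, 1]``.
    """

    def __init__(self, spec: NetworkSpec, seed: int):
        spec.validate()
        self.spec = spec
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        act = spec.resolved_activation()
        self._act_kind = act
        self.conv_layers: list = []
        self.pools: dict = {}
        self.dense_layers: list = []
        self.bns: list = []
        if spec.kind == "mlp":
            sizes = spec.layer_sizes
            for i in range(len(sizes) - 1):
                self.dense_layers.append(
                    DenseLayer(sizes[i], sizes[i + 1], spec.binary, rng))
                self.bns.append(BatchNorm(sizes[i + 1]) if spec.batch_norm else None)
            self.dropout = spec.dropout or (0.0,) * (len(sizes) - 1)
        else:
            c_prev = spec.input_shape[0]
            h = spec.input_shape[1]
            for i, c_out in enumerate(spec.conv_channels):
                self.conv_layers.append(ConvLayer(c_prev, c_out, spec.binary, rng))
                c_prev = c_out
                if i % 2 == 1:
                    self.pools[i] = MaxPool2()
                    h //= 2
            flat = c_prev * h * h
            sizes = (flat,) + tuple(spec.dense_sizes)
            for i in range(len(sizes) - 1):
                self.dense_layers.append(
                    DenseLayer(sizes[i], sizes[i + 1], spec.binary, rng))
                self.bns.append(BatchNorm(sizes[i + 1]) if spec.batch_norm else None)
            self.conv_bns = [BatchNorm(c) for c in spec.conv_channels] if spec.batch_norm \
                else [None] * len(spec.conv_channels)
            self.dropout = spec.dropout or (0.0,) * (len(sizes) - 1)
        self._train_rng = np.random.default_rng(self.seed + 1)

    # -- parameter access ---------------------------------------------------

    def weight_layers(self):
        return self.conv_layers + self.dense_layers

    def hidden_weights(self):
        """List of hidden-weight arrays (views, mutable in place)."""
        return [lyr.hidden for lyr in self.weight_layers()]

    def binary_weights(self):
        return [binarize(lyr.hidden) for lyr in self.weight_layers()]

    def n_parameters(self) -> int:
        return int(sum(l.hidden.size for l in self.weight_layers()))

    def all_batchnorms(self):
        out = list(getattr(self, "conv_bns", [])) + list(self.bns)
        return [bn for bn in out if bn is not None]

    def use_bn_slot(self, slot: int, create: bool = True) -> None:
        for bn in self.all_batchnorms():
            bn.use_slot(slot, create=create)

    def bn_parameters(self):
        """Active-slot (gamma, beta) pairs, in a stable order."""
        return [(bn.state["gamma"], bn.state["beta"]) for bn in self.all_batchnorms()]

    # -- forward / backward -------------------------------------------------

    def _make_act(self):
        return _SignAct() if self._act_kind == "sign" else _TanhAct()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Compute class scores; caches intermediates for :meth:`backward`."""
        x = np.asarray(x, dtype=float)
        self._training = training
        self._acts = []
        self._drop_masks = []
        if self.spec.kind == "conv":
            for i, conv in enumerate(self.conv_layers):
                x = conv.forward(x)
                bn = self.conv_bns[i]
                if bn is not None:
                    n, c, h, w = x.shape
                    flat = x.transpose(0, 2, 3, 1).reshape(-1, c)
                    flat = bn.forward(flat, training)
                    x = flat.reshape(n, h, w, c).transpose(0, 3, 1, 2)
                act = self._make_act()
                x = act.forward(x)
                self._acts.append(act)
                if i in self.pools:
                    x = self.pools[i].forward(x)
            self._conv_out_shape = x.shape
            x = x.reshape(x.shape[0], -1)
        n_dense = len(self.dense_layers)
        for i, lyr in enumerate(self.dense_layers):
            p = self.dropout[i] if i < len(self.dropout) else 0.0
            if training and p > 0.0:
                mask = (self._train_rng.random(x.shape) >= p) / (1.0 - p)
                x = x * mask
                self._drop_masks.append(mask)
            else:
                self._drop_masks.append(None)
            x = lyr.forward(x)
            bn = self.bns[i]
            if bn is not None:
                x = bn.forward(x, training)
            if i < n_dense - 1:
                act = self._make_act()
                x = act.forward(x)
                self._acts.append(act)
        return x

    def backward(self, dscores: np.ndarray):
        """Backpropagate from score gradients.

        Returns ``(weight_grads, bn_grads)`` where ``weight_grads`` aligns
        with :meth:`weight_layers` and ``bn_grads`` holds ``(dgamma, dbeta)``
        aligned with :meth:`all_batchnorms`.  Weight gradients are taken with
        respect to the *binary* weights (the values used in the forward
        pass); the sign non-differentiability is bridged by the STE.
        """
        if not hasattr(self, "_acts"):
            raise RuntimeError("backward called before forward (missing cache)")
        training = self._training
        acts = list(self._acts)
        n_dense = len(self.dense_layers)
        dense_grads = [None] * n_dense
        bn_grads_dense = [None] * n_dense
        dy = dscores
        for i in range(n_dense - 1, -1, -1):
            if i < n_dense - 1:
                dy = acts.pop().backward(dy)
            bn = self.bns[i]
            if bn is not None:
                dy, dg, db = bn.backward(dy, training)
                bn_grads_dense[i] = (dg, db)
            dy, dw = self.dense_layers[i].backward(dy)
            dense_grads[i] = dw
            mask = self._drop_masks[i]
            if mask is not None:
                dy = dy * mask
        conv_grads = []
        bn_grads_conv = []
        if self.spec.kind == "conv":
            dy = dy.reshape(self._conv_out_shape)
            n_conv = len(self.conv_layers)
            conv_grads = [None] * n_conv
            bn_grads_conv = [None] * n_conv
            for i in range(n_conv - 1, -1, -1):
                if i in self.pools:
                    dy = self.pools[i].backward(dy)
                dy = acts.pop().backward(dy)
                bn = self.conv_bns[i]
                if bn is not None:
                    n, c, h, w = dy.shape
                    flat = dy.transpose(0, 2, 3, 1).reshape(-1, c)
                    flat, dg, db = bn.backward(flat, training)
                    dy = flat.reshape(n, h, w, c).transpose(0, 3, 1, 2)
                    bn_grads_conv[i] = (dg, db)
                dy, dw = self.conv_layers[i].backward(dy)
                conv_grads[i] = dw
        weight_grads = conv_grads + dense_grads
        bn_grads = [g for g in (bn_grads_conv + bn_grads_dense) if g is not None]
        return weight_grads, bn_grads

    # -- loss ---------------------------------------------------------------

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray, training: bool = True):
        """Mean softmax cross-entropy and its gradients.

        Returns ``(loss, weight_grads, bn_grads)``.
        """
        scores = self.forward(x, training=training)
        probs = softmax(scores)
        n = scores.shape[0]
        loss = -np.mean(np.log(probs[np.arange(n), y] + 1e-12))
        dscores = probs.copy()
        dscores[np.arange(n), y] -= 1.0
        dscores /= n
        wg, bg = self.backward(dscores)
        return loss, wg, bg

    def predict_scores(self, x: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        outs = []
        for i in range(0, x.shape[0], batch_size):
            outs.append(self.forward(x[i:i + batch_size], training=False))
        return np.concatenate(outs, axis=0)

    def accuracy(self, x: np.ndarray, y: np.ndarray) -> float:
        """Test accuracy in percent."""
        pred = np.argmax(self.predict_scores(x), axis=1)
        return 100.0 * float(np.mean(pred == np.asarray(y)))


def softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def build_network(spec: NetworkSpec, seed: int = 0) -> Network:
    """Build a network with reproducible fan-in-scaled uniform initialization."""
    return Network(spec, seed)


# ---------------------------------------------------------------------------
# Checkpoints


def _spec_to_json(spec: NetworkSpec) -> str:
    return json.dumps(asdict(spec), sort_keys=True)


def _spec_from_json(s: str) -> NetworkSpec:
    d = json.loads(s)
    for k in ("layer_sizes", "conv_channels", "dense_sizes", "input_shape", "dropout"):
        d[k] = tuple(d[k])
    return NetworkSpec(**d)


def save_checkpoint(path, net: Network, optimizer_state: Optional[dict] = None) -> None:
    """Serialize hidden weights, all batch-norm slots and (optionally) the
    optimizer state into a single zip archive.  Deterministic member order
    and zeroed timestamps make save -> load -> save byte-identical."""
    arrays = {}
    for i, lyr in enumerate(net.weight_layers()):
        arrays[f"weight/{i}/hidden"] = lyr.hidden
    for i, bn in enumerate(net.all_batchnorms()):
        for slot, st in sorted(bn.slots.items()):
            for k, v in sorted(st.items()):
                arrays[f"bn/{i}/slot{slot}/{k}"] = v
    meta = {
        "spec": json.loads(_spec_to_json(net.spec)),
        "seed": net.seed,
        "bn_active": [bn.active for bn in net.all_batchnorms()],
        "optimizer": None,
    }
    if optimizer_state is not None:
        opt_arrays = {}
        opt_meta = {}
        for k, v in sorted(optimizer_state.items()):
            if isinstance(v, np.ndarray):
                arrays[f"opt/{k}"] = v
                opt_arrays[k] = True
            else:
                opt_meta[k] = v
        meta["optimizer"] = {"scalars": opt_meta, "arrays": sorted(opt_arrays)}
    with zipfile.ZipFile(path, "w", zipfile.ZIP_STORED) as zf:
        def _write(name, data):
            info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, data)

        _write("meta.json", json.dumps(meta, sort_keys=True))
        for name in sorted(arrays):
            buf = io.BytesIO()
            np.save(buf, np.ascontiguousarray(arrays[name]))
            _write(name + ".npy", buf.getvalue())


def load_checkpoint(path):
    """Inverse of :func:`save_checkpoint`; returns ``(network, optimizer_state)``."""
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        arrays = {}
        for name in zf.namelist():
            if name.endswith(".npy"):
                arrays[name[:-4]] = np.load(io.BytesIO(zf.read(name)))
    spec = _spec_from_json(json.dumps(meta["spec"]))
    net = Network(spec, meta["seed"])
    for i, lyr in enumerate(net.weight_layers()):
        lyr.hidden[...] = arrays[f"weight/{i}/hidden"]
    for i, bn in enumerate(net.all_batchnorms()):
        slots = sorted({k.split("/")[2] for k in arrays if k.startswith(f"bn/{i}/")})
        for slot_name in slots:
            slot = int(slot_name[4:])
            bn.use_slot(slot)
            for k in ("gamma", "beta", "running_mean", "running_var"):
                bn.slots[slot][k] = arrays[f"bn/{i}/{slot_name}/{k}"].copy()
        bn.active = meta["bn_active"][i]
    opt_state = None
    if meta.get("optimizer") is not None:
        opt_state = dict(meta["optimizer"]["scalars"])
        for k in meta["optimizer"]["arrays"]:
            opt_state[k] = arrays[f"opt/{k}"]
    return net, opt_state
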
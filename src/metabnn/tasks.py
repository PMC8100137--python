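"""Task construction for continual-learning protocols.

Covers the permuted-task construction (one fixed feature permutation per
task), stream sharding of a single dataset into disjoint subsets, the
interleaved (non-sequential) mixture baseline, IDX-format readers/writers for
the MNIST-layout image datasets, and a synthetic Gaussian-prototype task
generator that reproduces the permuted-task structure without any downloads.
"""

from __future__ import annotations

import gzip
import struct
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Dataset",
    "TaskSpec",
    "TaskSequence",
    "SyntheticTaskSpec",
    "make_permutation_task",
    "make_stream_shards",
    "generate_synthetic_tasks",
    "interleaved_mixture",
    "read_idx",
    "write_idx",
    "scale_to_unit_range",
]


@dataclass
class Dataset:
    """A labeled split pair; features are flat float arrays in [-1, 1]."""

    x_train: np.ndarray
    y_train: np.ndarray
    x_test: np.ndarray
    y_test: np.ndarray

    @property
    def n_features(self) -> int:
        return self.x_train.shape[1]

    @property
    def n_classes(self) -> int:
        return int(max(self.y_train.max(), self.y_test.max())) + 1


@dataclass
class TaskSpec:
    """One task of a sequence: a dataset plus its transform and BN slot."""

    data: Dataset
    permutation: np.ndarray | None = None  # None = identity
    bn_slot: int = 0
    name: str = ""

    def apply(self, x: np.ndarray) -> np.ndarray:
        if self.permutation is None:
            return x
        return x[:, self.permutation]

    @property
    def train(self):
        return self.apply(self.data.x_train), self.data.y_train

    @property
    def test(self):
        return self.apply(self.data.x_test), self.data.y_test


@dataclass
class TaskSequence:
    tasks: list

    def __len__(self):
        return len(self.tasks)

    def __getitem__(self, i):
        return self.tasks[i]

    def __iter__(self):
        return iter(self.tasks)


@dataclass(frozen=True)
class SyntheticTaskSpec:
    """Gaussian-prototype classification: each class is an isotropic Gaussian
    around a random prototype, labels are the generating prototype's class.

    Only a fraction of the coordinates is informative; the rest are constant
    (zero prototype, zero noise), mirroring image data where background
    pixels are blank.  Synaptic importance is then heterogeneous and
    concentrated — the structure the importance-based consolidation
    baselines rely on — and a coordinate permutation relocates the
    informative set, as pixel permutation does.

    Defaults give a 10-class problem in 64 dimensions learnable to the
    mid-90s in percent but with a non-vanishing loss, so that forgetting —
    not task difficulty — dominates continual-learning experiments.
    """

    n_classes: int = 10
    n_features: int = 64
    informative_fraction: float = 0.5
    prototype_scale: float = 1.4
    noise_sd: float = 2.0
    n_train_per_class: int = 200
    n_test_per_class: int = 50
    seed: int = 0


def _synthetic_base(spec: SyntheticTaskSpec) -> Dataset:
    rng = np.random.default_rng(spec.seed)
    n_info = max(2, int(round(spec.informative_fraction * spec.n_features)))
    info = rng.choice(spec.n_features, size=n_info, replace=False)

    def draw_protos():
        p = np.zeros((spec.n_classes, spec.n_features))
        p[:, info] = rng.normal(0.0, spec.prototype_scale,
                                size=(spec.n_classes, n_info))
        return p

    protos = draw_protos()
    # distinctness guard; astronomically unlikely to trigger
    for _ in range(10):
        d = np.linalg.norm(protos[:, None] - protos[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() > 1e-6:
            break
        protos = draw_protos()

    # Bayes-degeneracy warning: prototypes a few noise-sd apart or closer
    if d.min() < spec.noise_sd:
        warnings.warn("synthetic task is near-degenerate: class separation "
                      "below the noise scale (accuracy will be near chance)")

    def draw(n_per_class):
        xs, ys = [], []
        for c in range(spec.n_classes):
            noise = np.zeros((n_per_class, spec.n_features))
            noise[:, info] = rng.normal(0.0, spec.noise_sd, size=(n_per_class, n_info))
            xs.append(protos[c] + noise)
            ys.append(np.full(n_per_class, c, dtype=int))
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        perm = rng.permutation(len(y))
        return x[perm], y[perm]

    x_train, y_train = draw(spec.n_train_per_class)
    x_test, y_test = draw(spec.n_test_per_class)
    scale = np.max(np.abs(np.concatenate([x_train, x_test])))
    return Dataset(x_train / scale, y_train, x_test / scale, y_test)


def make_permutation_task(base: Dataset, seed: int, bn_slot: int = 0,
                          name: str = "") -> TaskSpec:
    """Task with one fixed feature permutation applied identically to every
    train and test example.  ``seed=0`` is the identity (the unpermuted base
    task by convention); other seeds draw a uniform random permutation."""
    if seed == 0:
        perm = None
    else:
        perm = np.random.default_rng(seed).permutation(base.n_features)
    return TaskSpec(data=base, permutation=perm, bn_slot=bn_slot,
                    name=name or f"perm{seed}")


def generate_synthetic_tasks(spec: SyntheticTaskSpec, n_tasks: int,
                             task_specific_bn: bool = True) -> TaskSequence:
    """Permuted-task sequence over one synthetic base dataset.

    Task 0 is the unpermuted base; tasks 1..n-1 apply coordinate
    permutations drawn from the spec seed, mirroring the permuted-image
    protocol.  Fully reproducible from ``spec.seed``.
    """
    base = _synthetic_base(spec)
    tasks = []
    for k in range(n_tasks):
        perm_seed = 0 if k == 0 else spec.seed * 1000 + k
        slot = k if task_specific_bn else 0
        tasks.append(make_permutation_task(base, perm_seed, bn_slot=slot,
                                           name=f"task{k}"))
    return TaskSequence(tasks)


def make_stream_shards(dataset_size: int, n_shards: int, shard_size: int,
                       seed: int = 0, labels: np.ndarray | None = None):
    """Disjoint shuffled index shards of a dataset.

    With ``labels`` given, sharding is stratified so every shard represents
    all classes (as in stream protocols where each subset contains every
    class).  Shards are order-preserving lists of 0-based indices.
    """
    if n_shards * shard_size > dataset_size:
        raise ValueError(
            f"{n_shards} shards of {shard_size} oversubscribe {dataset_size} examples")
    rng = np.random.default_rng(seed)
    if labels is None:
        order = rng.permutation(dataset_size)[: n_shards * shard_size]
        return [np.sort(order[i * shard_size:(i + 1) * shard_size])
                for i in range(n_shards)]
    labels = np.asarray(labels)
    # build one deck that cycles through the classes, then cut consecutive
    # shard_size blocks: every shard sees all classes (given shard_size >=
    # n_classes) and disjointness is automatic
    per_class = [rng.permutation(np.flatnonzero(labels == c))
                 for c in np.unique(labels)]
    deck = []
    depth = max(len(m) for m in per_class)
    for j in range(depth):
        for m in per_class:
            if j < len(m):
                deck.append(int(m[j]))
    quota = n_shards * shard_size
    if len(deck) < quota:
        raise ValueError("not enough labeled examples for the requested shards")
    deck = np.asarray(deck[:quota])
    return [np.sort(deck[i * shard_size:(i + 1) * shard_size])
            for i in range(n_shards)]


def interleaved_mixture(tasks: TaskSequence, seed: int = 0):
    """Non-sequential baseline: all tasks' training examples pooled.

    Returns ``(x, y, task_id)`` concatenated and shuffled once; training
    loops reshuffle per epoch.  Evaluation remains per-task.
    """
    if len(tasks) == 0:
        raise ValueError("interleaved_mixture needs at least one task")
    xs, ys, ts = [], [], []
    for k, task in enumerate(tasks):
        x, y = task.train
        xs.append(x)
        ys.append(y)
        ts.append(np.full(len(y), k, dtype=int))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    t = np.concatenate(ts)
    perm = np.random.default_rng(seed).permutation(len(y))
    return x[perm], y[perm], t[perm]


# ---------------------------------------------------------------------------
# IDX container (MNIST-layout) I/O

_IDX_DTYPES = {0x08: np.uint8, 0x09: np.int8, 0x0B: ">i2", 0x0C: ">i4",
               0x0D: ">f4", 0x0E: ">f8"}
_IDX_CODES = {np.dtype(np.uint8): 0x08, np.dtype(np.int8): 0x09}


def _open_maybe_gzip(path, mode):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_idx(path) -> np.ndarray:
    """Read an IDX (big-endian magic header) array; gzip accepted.

    Returns the array with its header-declared shape; image scaling to
    ``[-1, 1]`` is applied downstream, not here.
    """
    with _open_maybe_gzip(path, "rb") as fh:
        magic = fh.read(4)
        if len(magic) != 4 or magic[0] != 0 or magic[1] != 0:
            raise ValueError(f"bad IDX magic in {path}")
        code, ndim = magic[2], magic[3]
        if code not in _IDX_DTYPES:
            raise ValueError(f"unknown IDX type code 0x{code:02x}")
        dims = struct.unpack(f">{ndim}I", fh.read(4 * ndim))
        data = fh.read()
    arr = np.frombuffer(data, dtype=_IDX_DTYPES[code])
    if arr.size != int(np.prod(dims)):
        raise ValueError(f"truncated IDX payload in {path}: "
                         f"expected {int(np.prod(dims))} items, got {arr.size}")
    return arr.reshape(dims)


def write_idx(path, arr: np.ndarray) -> None:
    """Write an array in IDX layout (uint8/int8); gzip by ``.gz`` suffix."""
    arr = np.asarray(arr)
    code = _IDX_CODES.get(arr.dtype)
    if code is None:
        raise ValueError(f"unsupported IDX dtype {arr.dtype}")
    with _open_maybe_gzip(path, "wb") as fh:
        fh.write(bytes([0, 0, code, arr.ndim]))
        fh.write(struct.pack(f">{arr.ndim}I", *arr.shape))
        fh.write(arr.tobytes())


def load_idx_dataset(images_path, labels_path):
    """Read an images/labels IDX pair, flatten images, check consistency."""
    images = read_idx(images_path)
    labels = read_idx(labels_path).astype(int)
    if images.shape[0] != labels.shape[0]:
        raise ValueError(
            f"label count {labels.shape[0]} != image count {images.shape[0]}")
    return images.reshape(images.shape[0], -1), labels


def scale_to_unit_range(x: np.ndarray, lo: float = 0.0, hi: float = 255.0):
    """Affine map of raw feature values from [lo, hi] to [-1, 1]."""
    return (np.asarray(x, dtype=float) - lo) / (hi - lo) * 2.0 - 1.0
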
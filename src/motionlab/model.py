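"""The three-stage velocity-regression network and its training loop.

Architecture (by analogy with the primate dorsal stream):

* **V1**: 64 three-dimensional kernels (6 x 6 px x 6 frames) correlated
  (valid mode) with the 32 x 32 x 6 input, plus a per-kernel offset and
  ReLU.  Time collapses (6 - 6 + 1 = 1), leaving 64 maps of 27 x 27.
* **MT**: a dense layer mapping all 64*27*27 = 46,656 rectified V1
  activities to 64 units (affine + ReLU).
* **Output**: two linear regression units estimating horizontal (v_x)
  and vertical (v_y) image velocity in px/frame.

Training is plain mini-batch SGD on the mean-squared velocity error
with a constant learning rate; gradients are computed by hand-coded
backpropagation (the model is small enough that an autodiff framework
buys nothing), and are validated against central finite differences in
the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .corpus import Corpus, MotionSequence

__all__ = [
    "ArchConfig",
    "ModelParams",
    "LayerActivities",
    "TrainConfig",
    "TrainingHistory",
    "VelocityEstimate",
    "init_model",
    "forward",
    "forward_batch",
    "count_connections",
    "train",
    "evaluate",
    "to_polar",
    "persist_model",
    "load_model",
]


@dataclass(frozen=True)
class ArchConfig:
    n_kernels: int = 64
    kernel_size: tuple[int, int, int] = (6, 6, 6)  # (y, x, t)
    input_size: tuple[int, int, int] = (32, 32, 6)
    n_mt_units: int = 64
    n_outputs: int = 2

    def __post_init__(self) -> None:
        if min(self.n_kernels, self.n_mt_units, self.n_outputs) < 1:
            raise ValueError("all unit counts must be positive")
        if any(k > i for k, i in zip(self.kernel_size, self.input_size)):
            raise ValueError("kernel extent exceeds input extent")

    @property
    def map_size(self) -> tuple[int, int, int]:
        """Valid-correlation output extent per kernel (y, x, t)."""
        return tuple(i - k + 1 for i, k in zip(self.input_size, self.kernel_size))

    @property
    def n_v1_units(self) -> int:
        h, w, t = self.map_size
        return self.n_kernels * h * w * t

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_kernels": self.n_kernels,
                "kernel_size": list(self.kernel_size),
                "input_size": list(self.input_size),
                "n_mt_units": self.n_mt_units,
                "n_outputs": self.n_outputs,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "ArchConfig":
        d = json.loads(s)
        return cls(
            n_kernels=d["n_kernels"],
            kernel_size=tuple(d["kernel_size"]),
            input_size=tuple(d["input_size"]),
            n_mt_units=d["n_mt_units"],
            n_outputs=d["n_outputs"],
        )


@dataclass
class ModelParams:
    """All learnable weights and offsets of the network.

    The flattened V1 index used by ``mt_weights`` is kernel-major:
    ``index = kernel * (map_h * map_w) + row * map_w + col``.
    """

    arch: ArchConfig
    v1_kernels: np.ndarray  # (n_kernels, ky, kx, kt)
    v1_offsets: np.ndarray  # (n_kernels,)
    mt_weights: np.ndarray  # (n_mt, n_v1_units)
    mt_offsets: np.ndarray  # (n_mt,)
    out_weights: np.ndarray  # (n_outputs, n_mt)
    out_offsets: np.ndarray  # (n_outputs,)
    seed: int | None = None
    trained_epochs: int = 0

    def validate(self) -> None:
        a = self.arch
        expect = {
            "v1_kernels": (a.n_kernels, *a.kernel_size),
            "v1_offsets": (a.n_kernels,),
            "mt_weights": (a.n_mt_units, a.n_v1_units),
            "mt_offsets": (a.n_mt_units,),
            "out_weights": (a.n_outputs, a.n_mt_units),
            "out_offsets": (a.n_outputs,),
        }
        for name, shape in expect.items():
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")

    def copy(self) -> "ModelParams":
        return ModelParams(
            arch=self.arch,
            v1_kernels=self.v1_kernels.copy(),
            v1_offsets=self.v1_offsets.copy(),
            mt_weights=self.mt_weights.copy(),
            mt_offsets=self.mt_offsets.copy(),
            out_weights=self.out_weights.copy(),
            out_offsets=self.out_offsets.copy(),
            seed=self.seed,
            trained_epochs=self.trained_epochs,
        )


@dataclass
class LayerActivities:
    """Activities of one sequence at every stage of the network."""

    v1: np.ndarray  # (n_kernels, map_h, map_w), rectified
    mt: np.ndarray  # (n_mt,), rectified
    output: np.ndarray  # (n_outputs,) = (v_x, v_y) estimate


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1.0e-4
    batch_size: int = 32
    epochs: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    test_loss: list[float] = field(default_factory=list)


@dataclass
class VelocityEstimate:
    v_x: float
    v_y: float
    speed: float
    direction: float | None  # degrees in [0, 360); None when speed == 0

    @property
    def direction_defined(self) -> bool:
        return self.direction is not None


def init_model(
    arch: ArchConfig = ArchConfig(),
    seed: int = 0,
    kernel_sd: float = 0.001,
    hidden_init: str = "glorot",
) -> ModelParams:
    """Initialise the network.

    V1 kernels start as Gaussian noise (mean 0, SD ``kernel_sd``) and all
    offsets at zero.  The dense and regression weights use Glorot-uniform
    initialisation by default: an all-zero affine stack is a stationary
    point of gradient descent (no gradient reaches zero-weight hidden
    layers), so ``hidden_init='zero'`` produces a network that cannot
    train and exists only for inspection.
    """
    rng = np.random.default_rng(seed)
    kernels = rng.normal(0.0, kernel_sd, size=(arch.n_kernels, *arch.kernel_size))
    if hidden_init == "glorot":
        lim_mt = np.sqrt(6.0 / (arch.n_v1_units + arch.n_mt_units))
        lim_out = np.sqrt(6.0 / (arch.n_mt_units + arch.n_outputs))
        mt_w = rng.uniform(-lim_mt, lim_mt, size=(arch.n_mt_units, arch.n_v1_units))
        out_w = rng.uniform(-lim_out, lim_out, size=(arch.n_outputs, arch.n_mt_units))
    elif hidden_init == "zero":
        mt_w = np.zeros((arch.n_mt_units, arch.n_v1_units))
        out_w = np.zeros((arch.n_outputs, arch.n_mt_units))
    else:
        raise ValueError(f"unknown hidden_init {hidden_init!r}")
    return ModelParams(
        arch=arch,
        v1_kernels=kernels,
        v1_offsets=np.zeros(arch.n_kernels),
        mt_weights=mt_w,
        mt_offsets=np.zeros(arch.n_mt_units),
        out_weights=out_w,
        out_offsets=np.zeros(arch.n_outputs),
        seed=seed,
    )


def _im2col(batch: np.ndarray, arch: ArchConfig) -> np.ndarray:
    """(N, H, W, T) -> (N, map_h*map_w*map_t, ky*kx*kt) patch matrix."""
    ky, kx, kt = arch.kernel_size
    win = sliding_window_view(batch, (ky, kx, kt), axis=(1, 2, 3))
    n = batch.shape[0]
    return win.reshape(n, -1, ky * kx * kt)


def _forward_arrays(
    params: ModelParams, batch: np.ndarray, return_cols: bool = False
):
    """Vectorised forward pass on a (N, H, W, T) stimulus stack.

    Returns (v1, v1_flat, mt, out[, cols]) where v1 is (N, n_pos,
    n_kernels) rectified, v1_flat is the kernel-major flattening used by
    the dense layer, mt is (N, n_mt) rectified and out is (N, 2).
    """
    arch = params.arch
    if batch.shape[1:] != arch.input_size:
        raise ValueError(
            f"stimulus extent {batch.shape[1:]} != input extent {arch.input_size}"
        )
    cols = _im2col(batch, arch)  # (N, n_pos, k)
    kmat = params.v1_kernels.reshape(arch.n_kernels, -1)
    pre = cols @ kmat.T + params.v1_offsets  # (N, n_pos, n_kernels)
    v1 = np.maximum(pre, 0.0)
    # kernel-major flattening: (N, n_kernels, n_pos)
    v1_flat = v1.transpose(0, 2, 1).reshape(batch.shape[0], -1)
    mt = np.maximum(v1_flat @ params.mt_weights.T + params.mt_offsets, 0.0)
    out = mt @ params.out_weights.T + params.out_offsets
    if return_cols:
        return v1, v1_flat, mt, out, cols
    return v1, v1_flat, mt, out


def forward_batch(params: ModelParams, batch: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward a (N, H, W, T) stack; returns (v1_flat, mt, out)."""
    _, v1_flat, mt, out = _forward_arrays(params, np.asarray(batch))
    return v1_flat, mt, out


def forward(params: ModelParams, seq: MotionSequence | np.ndarray) -> LayerActivities:
    """Forward a single sequence through all three stages."""
    frames = seq.frames if isinstance(seq, MotionSequence) else np.asarray(seq)
    arch = params.arch
    v1, _, mt, out = _forward_arrays(params, frames[None])
    h, w, t = arch.map_size
    shape = (arch.n_kernels, h, w) if t == 1 else (arch.n_kernels, h, w, t)
    v1_maps = v1[0].T.reshape(shape)
    return LayerActivities(v1=v1_maps, mt=mt[0], output=out[0])


def count_connections(params: ModelParams | ArchConfig) -> dict[str, dict[str, int]]:
    """Per-layer (connections, learnable parameters) from shapes alone."""
    arch = params if isinstance(params, ArchConfig) else params.arch
    h, w, t = arch.map_size
    n_pos = h * w * t
    k = int(np.prod(arch.kernel_size))
    v1_conn = arch.n_kernels * n_pos * k
    v1_params = arch.n_kernels * k + arch.n_kernels
    mt_conn = arch.n_mt_units * arch.n_v1_units
    mt_params = mt_conn + arch.n_mt_units
    out_conn = arch.n_outputs * arch.n_mt_units
    out_params = out_conn + arch.n_outputs
    return {
        "v1": {"connections": v1_conn, "parameters": v1_params},
        "mt": {"connections": mt_conn, "parameters": mt_params},
        "output": {"connections": out_conn, "parameters": out_params},
    }


def _loss_and_grads(params: ModelParams, batch: np.ndarray, labels: np.ndarray):
    """Loss and hand-coded backprop gradients.

    The loss is the squared velocity error ``|v_hat - v|**2`` averaged
    over the batch (summed over the two components).
    """
    n = batch.shape[0]
    arch = params.arch
    v1, v1_flat, mt, out, cols = _forward_arrays(params, batch, return_cols=True)
    err = out - labels
    loss = float(np.sum(err**2) / n)
    dout = (2.0 / n) * err  # (N, 2)
    g_out_w = dout.T @ mt
    g_out_b = dout.sum(axis=0)
    dmt = (dout @ params.out_weights) * (mt > 0)
    g_mt_w = dmt.T @ v1_flat
    g_mt_b = dmt.sum(axis=0)
    dv1_flat = dmt @ params.mt_weights  # (N, n_v1)
    n_pos = v1.shape[1]
    dv1 = dv1_flat.reshape(n, arch.n_kernels, n_pos).transpose(0, 2, 1)
    dv1 = dv1 * (v1 > 0)
    kdim = cols.shape[2]
    g_k = dv1.reshape(n * n_pos, arch.n_kernels).T @ cols.reshape(n * n_pos, kdim)
    g_v1_b = dv1.sum(axis=(0, 1))
    grads = {
        "v1_kernels": g_k.reshape(params.v1_kernels.shape),
        "v1_offsets": g_v1_b,
        "mt_weights": g_mt_w,
        "mt_offsets": g_mt_b,
        "out_weights": g_out_w,
        "out_offsets": g_out_b,
    }
    return loss, grads


def _mse(params: ModelParams, batch: np.ndarray, labels: np.ndarray, chunk: int = 256) -> float:
    """Squared velocity error averaged over sequences."""
    total = 0.0
    for i in range(0, batch.shape[0], chunk):
        _, _, out = forward_batch(params, batch[i : i + chunk])
        total += float(np.sum((out - labels[i : i + chunk]) ** 2))
    return total / batch.shape[0]


def _stack_split(split: list[MotionSequence], dtype=np.float64):
    x = np.stack([s.frames for s in split]).astype(dtype)
    y = np.array([[s.v_x, s.v_y] for s in split], dtype=np.float64)
    return x, y


def _cast_params(params: ModelParams, dtype) -> ModelParams:
    out = params.copy()
    for name in _PARAM_DSETS:
        setattr(out, name, getattr(out, name).astype(dtype))
    return out


def train(
    params: ModelParams,
    corpus: Corpus,
    cfg: TrainConfig = TrainConfig(),
    verbose: bool = False,
    dtype=np.float32,
    track_test_loss: bool = True,
) -> tuple[ModelParams, TrainingHistory]:
    """Plain SGD: ``w <- w - lr * dL/dw`` averaged over each mini-batch.

    Batches are a fresh random partition of the training set each epoch;
    the held-out loss is recorded once per epoch.  Deterministic given
    (initial params, corpus, cfg.seed).  Arithmetic runs in ``dtype``
    (single precision by default -- gradient noise of order 1e-7 is far
    below SGD's own stochasticity; pass ``np.float64`` for exact-update
    work such as gradient checks).
    """
    if not corpus.train:
        raise ValueError("corpus has no training sequences")
    params = _cast_params(params, dtype)
    params.validate()
    x_train, y_train = _stack_split(corpus.train, dtype=dtype)
    y_train = y_train.astype(dtype)
    x_test, y_test = (
        _stack_split(corpus.test, dtype=dtype)
        if corpus.test and track_test_loss
        else (None, None)
    )
    rng = np.random.default_rng(cfg.seed)
    history = TrainingHistory()
    names = ["v1_kernels", "v1_offsets", "mt_weights", "mt_offsets", "out_weights", "out_offsets"]
    n = x_train.shape[0]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss, grads = _loss_and_grads(params, x_train[idx], y_train[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}, batch {n_batches}: loss={loss}"
                )
            for name in names:
                arr = getattr(params, name)
                arr -= cfg.learning_rate * grads[name]
            epoch_loss += loss
            n_batches += 1
        history.train_loss.append(epoch_loss / n_batches)
        if x_test is not None:
            history.test_loss.append(_mse(params, x_test, y_test))
        if verbose:
            t = history.test_loss[-1] if history.test_loss else float("nan")
            print(f"epoch {epoch + 1}/{cfg.epochs}: train {history.train_loss[-1]:.4f} test {t:.4f}")
    params = _cast_params(params, np.float64)
    params.trained_epochs += cfg.epochs
    return params, history


def evaluate(
    params: ModelParams, sequences: list[MotionSequence], chunk: int = 256
) -> tuple[float, float]:
    """Pearson correlation (r_vx, r_vy) between estimates and ground truth."""
    if len(sequences) < 3:
        raise ValueError("need at least 3 sequences for a correlation")
    x, y = _stack_split(sequences)
    outs = []
    for i in range(0, x.shape[0], chunk):
        _, _, out = forward_batch(params, x[i : i + chunk])
        outs.append(out)
    est = np.concatenate(outs)
    rs = []
    for j in range(2):
        if est[:, j].std() == 0 or y[:, j].std() == 0:
            raise ValueError(f"zero-variance estimates for component {j}: correlation undefined")
        rs.append(float(np.corrcoef(est[:, j], y[:, j])[0, 1]))
    return rs[0], rs[1]


def to_polar(v_x: float, v_y: float) -> VelocityEstimate:
    """Convert Cartesian velocity to speed and direction.

    Direction is degrees counterclockwise from rightward (so (1, 0) maps
    to 0 deg), wrapped to [0, 360); at zero speed the direction is
    undefined and returned as None.
    """
    speed = float(np.hypot(v_x, v_y))
    if speed == 0.0:
        return VelocityEstimate(v_x=float(v_x), v_y=float(v_y), speed=0.0, direction=None)
    direction = float(np.degrees(np.arctan2(v_y, v_x)) % 360.0)
    return VelocityEstimate(v_x=float(v_x), v_y=float(v_y), speed=speed, direction=direction)


_PARAM_DSETS = ["v1_kernels", "v1_offsets", "mt_weights", "mt_offsets", "out_weights", "out_offsets"]
_FORMAT_VERSION = 1


def persist_model(params: ModelParams, path: str | Path) -> None:
    """Write the model to HDF5; the round trip is bit-exact."""
    params.validate()
    with h5py.File(path, "w") as f:
        for name in _PARAM_DSETS:
            f.create_dataset(name, data=getattr(params, name))
        f.attrs["arch"] = params.arch.to_json()
        f.attrs["format_version"] = _FORMAT_VERSION
        f.attrs["seed"] = -1 if params.seed is None else params.seed
        f.attrs["trained_epochs"] = params.trained_epochs


def load_model(path: str | Path) -> ModelParams:
    try:
        with h5py.File(path, "r") as f:
            if f.attrs.get("format_version") != _FORMAT_VERSION:
                raise IOError(f"{path}: unknown or missing model format version")
            arch = ArchConfig.from_json(f.attrs["arch"])
            arrays = {}
            for name in _PARAM_DSETS:
                if name not in f:
                    raise IOError(f"{path}: missing dataset {name}")
                arrays[name] = f[name][...]
            seed = int(f.attrs["seed"])
            params = ModelParams(
                arch=arch,
                seed=None if seed < 0 else seed,
                trained_epochs=int(f.attrs["trained_epochs"]),
                **arrays,
            )
    except OSError as e:
        raise IOError(f"cannot read model file {path}: {e}") from e
    params.validate()
    return params
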
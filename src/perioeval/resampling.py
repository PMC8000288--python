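"""Separable image resampling with classical interpolation kernels, plus a
small trainable super-resolution CNN (SRCNN-style).

Images are 2-D ``float64`` NumPy arrays in row-major order (row 0 = top).
Intensities are nominally on the 8-bit [0, 255] scale but are carried as
unbounded reals through processing; :func:`quantize_u8` performs the final
round-and-clip.

Coordinate convention
---------------------
Half-pixel centers: output pixel ``dst`` samples the input at

    src = (dst + 0.5) * (n_in / n_out) - 0.5

with clamp-to-edge boundary handling and per-output-pixel weight
normalization (each tap row is divided by its sum, so every kernel forms a
partition of unity and constant images are exactly invariant).

Kernels
-------
``nearest``     box of radius 0.5 (pure pixel replication at integer factors)
``triangle``    tent of radius 1 ("bilinear")
``keys_cubic``  Keys cubic with a = -0.5 ("bicubic")
``lanczos``     3-lobe windowed sinc, sinc(t)*sinc(t/3) on |t| < 3

The common names ``bilinear``/``bicubic``/``lanczos3`` are accepted as
aliases everywhere a kernel kind is expected.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "KERNEL_KINDS",
    "kernel_support",
    "kernel_weight",
    "resize",
    "resize_area",
    "quantize_u8",
    "SRCNNConfig",
    "SRCNNModel",
    "srcnn_apply",
    "srcnn_train",
    "save_srcnn",
    "load_srcnn",
]

# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

_SUPPORT = {"nearest": 0.5, "triangle": 1.0, "keys_cubic": 2.0, "lanczos": 3.0}

_ALIASES = {
    "bilinear": "triangle",
    "bicubic": "keys_cubic",
    "lanczos3": "lanczos",
    "box": "nearest",
}

KERNEL_KINDS = tuple(_SUPPORT)


def _canonical(kind: str) -> str:
    k = _ALIASES.get(kind, kind)
    if k not in _SUPPORT:
        raise ValueError(f"unknown kernel kind: {kind!r}")
    return k


def kernel_support(kind: str) -> float:
    """Support radius of the kernel (weight is 0 for |t| >= radius)."""
    return _SUPPORT[_canonical(kind)]


def kernel_weight(kind: str, t: float) -> float:
    """Analytic kernel value at signed offset ``t`` (pixels).

    ``keys_cubic`` is the Keys polynomial with a = -0.5; ``lanczos`` is the
    3-lobe windowed sinc. The nearest kernel is piecewise constant on the
    half-open interval [-0.5, 0.5) so each sample point has exactly one
    supporting tap.
    """
    kind = _canonical(kind)
    if kind == "nearest":
        return 1.0 if -0.5 <= t < 0.5 else 0.0
    a = abs(float(t))
    if kind == "triangle":
        return 1.0 - a if a < 1.0 else 0.0
    if kind == "keys_cubic":
        if a < 1.0:
            return (1.5 * a - 2.5) * a * a + 1.0
        if a < 2.0:
            return ((-0.5 * a + 2.5) * a - 4.0) * a + 2.0
        return 0.0
    # lanczos, 3 lobes
    if a >= 3.0:
        return 0.0
    if a < 1e-12:
        return 1.0
    x = math.pi * a
    return 3.0 * math.sin(x) * math.sin(x / 3.0) / (x * x)


# ---------------------------------------------------------------------------
# Separable resize
# ---------------------------------------------------------------------------


def _weight_matrix(n_in: int, n_out: int, kind: str) -> np.ndarray:
    """Dense (n_out, n_in) row-stochastic resampling matrix for one axis."""
    kind = _canonical(kind)
    support = _SUPPORT[kind]
    scale = n_in / n_out
    w = np.zeros((n_out, n_in))
    for d in range(n_out):
        src = (d + 0.5) * scale - 0.5
        if kind == "nearest":
            j = min(max(int(math.floor(src + 0.5)), 0), n_in - 1)
            w[d, j] = 1.0
            continue
        lo = int(math.floor(src - support)) + 1
        hi = int(math.floor(src + support))
        for j in range(lo, hi + 1):
            wt = kernel_weight(kind, src - j)
            if wt != 0.0:
                w[d, min(max(j, 0), n_in - 1)] += wt  # clamp-to-edge
        s = w[d].sum()
        if s == 0.0:  # cannot happen for the supported kernels; guard anyway
            raise ArithmeticError("degenerate tap row")
        w[d] /= s
    return w


def resize(
    image: np.ndarray,
    out_height: int,
    out_width: int,
    kind: str = "keys_cubic",
    quantize: bool = False,
) -> np.ndarray:
    """Resample ``image`` to ``(out_height, out_width)`` with a named kernel.

    Rows and columns are filtered separately (the kernels are separable, so
    this equals the full 2-D evaluation). Output stays in floating point
    unless ``quantize`` is set, in which case it is rounded half-away-from-
    zero, clipped to [0, 255] and returned as float (integer-valued).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if out_height < 1 or out_width < 1:
        raise ValueError("output dimensions must be >= 1")
    wr = _weight_matrix(image.shape[0], out_height, kind)
    wc = _weight_matrix(image.shape[1], out_width, kind)
    out = wr @ image @ wc.T
    return quantize_u8(out).astype(float) if quantize else out


def _area_weight_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Exact interval-overlap (area-average) matrix for one axis.

    Input pixel ``j`` covers [j, j+1); output pixel ``d`` covers
    [d*s, (d+1)*s) with s = n_in/n_out. Weight is the overlap length
    normalized by s, so the matrix is row stochastic for any size pair.
    """
    scale = n_in / n_out
    w = np.zeros((n_out, n_in))
    for d in range(n_out):
        left, right = d * scale, (d + 1) * scale
        j0, j1 = int(math.floor(left)), min(int(math.ceil(right)), n_in)
        for j in range(j0, j1):
            overlap = min(right, j + 1) - max(left, j)
            if overlap > 0:
                w[d, j] = overlap / scale
    return w


def resize_area(image: np.ndarray, out_height: int, out_width: int) -> np.ndarray:
    """Area-average downscale (box integration over exact pixel overlap).

    Used as the neutral downscaler in the degrade-then-restore protocol so
    no upscaling kernel is favored. For integer factors each output pixel is
    exactly the mean of its source block.
    """
    image = np.asarray(image, dtype=float)
    if out_height < 1 or out_width < 1:
        raise ValueError("output dimensions must be >= 1")
    wr = _area_weight_matrix(image.shape[0], out_height)
    wc = _area_weight_matrix(image.shape[1], out_width)
    return wr @ image @ wc.T


def quantize_u8(image: np.ndarray) -> np.ndarray:
    """Quantize to 8-bit: round half away from zero, clip to [0, 255]."""
    image = np.asarray(image, dtype=float)
    rounded = np.sign(image) * np.floor(np.abs(image) + 0.5)
    return np.clip(rounded, 0.0, 255.0).astype(np.uint8)


# ---------------------------------------------------------------------------
# SRCNN: three-stage convolutional super-resolution head
# ---------------------------------------------------------------------------
#
# Stage 1 extracts overlapping patches (large filter, many channels), stage 2
# maps them nonlinearly (1x1 mixing), stage 3 reconstructs a single-channel
# residual-free output. Rectification after stages 1-2, linear stage 3,
# zero same-padding throughout, so spatial size is preserved. The network
# operates on a bicubic (keys_cubic) pre-upscaled image normalized to [0, 1].


@dataclass
class SRCNNConfig:
    """Architecture and training hyper-parameters for the small SRCNN.

    ``filter_sizes``/``channels`` default to the shrunk desk-scale variant
    (9/1/5 filters, 16/8/1 channels). ``init_scale`` sets the spread of the
    random perturbation around the near-identity initialization, under which
    the untrained network reproduces (approximately) its bicubic input.
    """

    filter_sizes: tuple[int, int, int] = (9, 1, 5)
    channels: tuple[int, int] = (16, 8)
    learning_rate: float = 0.01
    n_iter: int = 300
    seed: int = 0
    init_scale: float = 1e-3


@dataclass
class SRCNNModel:
    weights: list[np.ndarray] = field(default_factory=list)  # (k, k, cin, cout)
    biases: list[np.ndarray] = field(default_factory=list)  # (cout,)

    def __post_init__(self) -> None:
        if len(self.weights) != 3 or len(self.biases) != 3:
            raise ValueError("SRCNN has exactly three stages")
        for i in range(3):
            cout = self.weights[i].shape[3]
            if self.biases[i].shape != (cout,):
                raise ValueError("bias/weight channel mismatch")
            if i and self.weights[i].shape[2] != self.weights[i - 1].shape[3]:
                raise ValueError("stage channel mismatch")


def _conv_same(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Zero same-padded stride-1 convolution, x: (N,H,W,Cin), w: (k,k,Cin,Cout)."""
    k = w.shape[0]
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    # win: (N, H, W, Cin, k, k) -> (N, H, W, k*k*Cin)
    n, h, wd = x.shape[0], x.shape[1], x.shape[2]
    cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n, h, wd, -1)
    return cols @ w.reshape(-1, w.shape[3]) + b


def _forward(model: SRCNNModel, x: np.ndarray) -> list[np.ndarray]:
    """Return per-stage activations [x, a1, a2, y] (ReLU after stages 1-2)."""
    acts = [x]
    a = x
    for i in range(3):
        a = _conv_same(a, model.weights[i], model.biases[i])
        if i < 2:
            a = np.maximum(a, 0.0)
        acts.append(a)
    return acts


def srcnn_apply(model: SRCNNModel, image: np.ndarray, factor: float) -> np.ndarray:
    """Upscale by ``factor`` (> 1): keys_cubic pre-upscale then the CNN.

    Returns a float image on the [0, 255] scale, same size as the
    pre-upscaled image; not quantized.
    """
    if factor <= 1:
        raise ValueError("factor must be > 1")
    image = np.asarray(image, dtype=float)
    oh = max(int(round(image.shape[0] * factor)), 1)
    ow = max(int(round(image.shape[1] * factor)), 1)
    up = resize(image, oh, ow, kind="keys_cubic")
    x = (up / 255.0)[None, :, :, None]
    y = _forward(model, x)[-1]
    return y[0, :, :, 0] * 255.0


def srcnn_init(config: SRCNNConfig) -> SRCNNModel:
    """Near-identity initialization: center taps pass channel 0 through, plus
    a small seeded random perturbation, so the initial network output is
    approximately the bicubic pre-upscale (a residual-friendly start)."""
    rng = np.random.default_rng(config.seed)
    k1, k2, k3 = config.filter_sizes
    c1, c2 = config.channels
    shapes = [(k1, k1, 1, c1), (k2, k2, c1, c2), (k3, k3, c2, 1)]
    weights = []
    for k, _k, cin, cout in shapes:
        w = rng.normal(0.0, config.init_scale, size=(k, _k, cin, cout))
        w[k // 2, _k // 2, 0, 0] += 1.0  # identity path on channel 0
        weights.append(w)
    biases = [np.zeros(s[3]) for s in shapes]
    return SRCNNModel(weights, biases)


def _loss_and_grads(model: SRCNNModel, x: np.ndarray, target: np.ndarray):
    acts = _forward(model, x)
    resid = acts[-1] - target
    loss = float(np.mean(resid**2))
    n_elem = resid.size
    d = 2.0 * resid / n_elem
    grads_w, grads_b = [None] * 3, [None] * 3
    for i in (2, 1, 0):
        a_in = acts[i]
        if i < 2:  # ReLU was applied to this stage's output
            d = d * (acts[i + 1] > 0.0)
        w = model.weights[i]
        k = w.shape[0]
        p = k // 2
        # dW: correlate input windows with upstream gradient
        xp = np.pad(a_in, ((0, 0), (p, p), (p, p), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(-1, k * k * a_in.shape[3])
        gw = (cols.T @ d.reshape(-1, d.shape[3])).reshape(w.shape)
        gb = d.sum(axis=(0, 1, 2))
        grads_w[i], grads_b[i] = gw, gb
        if i > 0:  # propagate: conv with spatially flipped, transposed filter
            w_rot = w[::-1, ::-1].transpose(0, 1, 3, 2)
            d = _conv_same(d, w_rot, np.zeros(w_rot.shape[3]))
    return loss, grads_w, grads_b


def srcnn_train(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    config: SRCNNConfig | None = None,
) -> tuple[SRCNNModel, dict]:
    """Train the three-stage network on (low-res, high-res) image pairs.

    All pairs must share the magnification factor. The low-res inputs are
    keys_cubic pre-upscaled to their targets' size, intensities normalized
    to [0, 1], and the mean squared reconstruction error is minimized by
    full-batch gradient descent. Returns the snapshot with the lowest
    recorded training loss (the initialization included) and a history dict
    with the per-iteration loss. Deterministic given ``config.seed``.
    """
    if not pairs:
        raise ValueError("at least one training pair required")
    config = config or SRCNNConfig()
    if config.learning_rate <= 0:
        raise ValueError("learning rate must be positive")
    factors = {round(hi.shape[0] / lo.shape[0], 6) for lo, hi in pairs}
    if len(factors) != 1:
        raise ValueError("all pairs must share the magnification factor")
    xs, ys = [], []
    for lo, hi in pairs:
        up = resize(np.asarray(lo, dtype=float), hi.shape[0], hi.shape[1], "keys_cubic")
        xs.append(up / 255.0)
        ys.append(np.asarray(hi, dtype=float) / 255.0)
    x = np.stack(xs)[..., None]
    y = np.stack(ys)[..., None]

    model = srcnn_init(config)
    best = {"loss": math.inf, "weights": None, "biases": None}
    losses = []
    for _ in range(config.n_iter):
        loss, gw, gb = _loss_and_grads(model, x, y)
        losses.append(loss)
        if loss < best["loss"]:
            best = {
                "loss": loss,
                "weights": [w.copy() for w in model.weights],
                "biases": [b.copy() for b in model.biases],
            }
        for i in range(3):
            model.weights[i] -= config.learning_rate * gw[i]
            model.biases[i] -= config.learning_rate * gb[i]
    final_loss, _, _ = _loss_and_grads(model, x, y)
    losses.append(final_loss)
    if final_loss < best["loss"]:
        best = {"loss": final_loss, "weights": model.weights, "biases": model.biases}
    trained = SRCNNModel(best["weights"], best["biases"])
    history = {"loss": losses, "best_loss": best["loss"], "initial_loss": losses[0]}
    return trained, history


def save_srcnn(model: SRCNNModel, path: str | Path) -> None:
    """Serialize as JSON with stage shapes and flattened weights (text only)."""
    payload = {
        "stages": [
            {
                "shape": list(w.shape),
                "weights": w.ravel().tolist(),
                "bias": b.tolist(),
            }
            for w, b in zip(model.weights, model.biases)
        ]
    }
    Path(path).write_text(json.dumps(payload))


def load_srcnn(path: str | Path) -> SRCNNModel:
    payload = json.loads(Path(path).read_text())
    weights, biases = [], []
    for st in payload["stages"]:
        weights.append(np.array(st["weights"]).reshape(st["shape"]))
        biases.append(np.array(st["bias"]))
    return SRCNNModel(weights, biases)
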
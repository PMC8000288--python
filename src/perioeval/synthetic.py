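"""Synthetic stand-ins for the clinical inputs: radiograph-like phantoms,
low-resolution degradations, simulated observer ratings, and simulated
binary-classifier scores.

The phantom is deliberately stylized — bright convex tooth strips on a dark
background, a bright alveolar-crest band bridging the interproximal gaps,
and an optional radiolucent crestal defect (horizontal loss, a vertical
wedge, or a trough-like crater) — because only the downstream mathematics
(resampling, quality metrics, VGC statistics, classifier evaluation) is
under test, not anatomical fidelity. Every generator is a pure function of
its spec and seed.

The observer simulator is a cumulative-threshold (ordered-categorical)
model: each rating's latent quality is method quality + observer bias +
Gaussian noise, and three increasing thresholds cut the latent scale into
the four MOS levels. This is the simplest model that yields the stochastic
ordering VGC analysis assumes, so latent orderings are recoverable from
pooled AUCs. The classifier simulator draws scores from two unit-spread
normals separated by ``separation_d`` and squashes them monotonically to
[0, 1], so its ROC-AUC follows the binormal closed form Phi(d / sqrt(2)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .resampling import resize, resize_area, quantize_u8

__all__ = [
    "LESION_KINDS",
    "PhantomSpec",
    "generate_phantom",
    "lesion_bbox",
    "lesion_mask",
    "degrade",
    "ObserverModel",
    "default_observer_model",
    "simulate_ratings",
    "ClassifierSimSpec",
    "simulate_classifier_scores",
    "save_png",
    "load_png",
]

LESION_KINDS = ("none", "horizontal", "vertical", "crater")

# piecewise-constant intensity levels of the noise-free phantom
LEVELS = {"background": 40.0, "tooth": 200.0, "crest": 150.0, "lesion": 60.0}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and degradation parameters of one phantom.

    ``lesion_depth`` is the defect depth as a fraction of the crest band
    height; ``noise_sd`` is additive Gaussian noise in intensity units on
    the [0, 255] scale; ``blur_sigma`` is in pixels. Blur is applied before
    noise, and the result is clipped to [0, 255].
    """

    height: int = 256
    width: int = 256
    n_teeth: int = 3
    lesion: str = "none"
    lesion_depth: float = 0.6
    noise_sd: float = 4.0
    blur_sigma: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 32 or self.width < 32:
            raise ValueError("phantom dimensions must be >= 32")
        if self.n_teeth < 1:
            raise ValueError("n_teeth must be >= 1")
        if self.lesion not in LESION_KINDS:
            raise ValueError(f"lesion must be one of {LESION_KINDS}")
        if not 0.0 <= self.lesion_depth <= 1.0:
            raise ValueError("lesion_depth must lie in [0, 1]")
        if self.noise_sd < 0 or self.blur_sigma < 0:
            raise ValueError("noise_sd and blur_sigma must be >= 0")
        if self.lesion != "none" and self.n_teeth < 2:
            raise ValueError("a lesion needs an interproximal gap (n_teeth >= 2)")


def _geometry(spec: PhantomSpec):
    """Column extents of teeth and gaps, and crest band rows."""
    w, h = spec.width, spec.height
    margin = int(round(0.06 * w))
    pitch = (w - 2 * margin) / spec.n_teeth
    gap = max(int(round(0.22 * pitch)), 2)
    teeth = []
    for t in range(spec.n_teeth):
        c0 = margin + int(round(t * pitch)) + gap // 2
        c1 = margin + int(round((t + 1) * pitch)) - gap // 2
        teeth.append((c0, max(c1, c0 + 1)))
    gaps = [(teeth[t][1], teeth[t + 1][0]) for t in range(spec.n_teeth - 1)]
    crest_top = int(round(0.52 * h))
    crest_h = max(int(round(0.12 * h)), 3)
    row_top = int(round(0.06 * h))
    row_bot = int(round(0.94 * h))
    return teeth, gaps, (crest_top, crest_h), (row_top, row_bot)


def lesion_mask(spec: PhantomSpec) -> np.ndarray:
    """Boolean mask of the pixels the lesion darkens (noise/blur off)."""
    mask = np.zeros((spec.height, spec.width), dtype=bool)
    if spec.lesion == "none" or spec.lesion_depth == 0.0:
        return mask
    _, gaps, (crest_top, crest_h), _ = _geometry(spec)
    g0, g1 = gaps[0]  # first interproximal gap hosts the defect
    depth = spec.lesion_depth * crest_h
    width = g1 - g0
    cols = np.arange(g0, g1)
    if spec.lesion == "horizontal":
        # symmetric loss of crest height across the whole gap
        per_col = np.full(width, depth)
    elif spec.lesion == "vertical":
        # uneven wedge, deepest against one tooth, tapering across the gap
        per_col = depth * (1.0 - (cols - g0) / max(width - 1, 1))
    else:  # crater: two-walled trough, deepest at the gap center
        u = (cols - g0) / max(width - 1, 1)
        per_col = depth * (1.0 - (2.0 * u - 1.0) ** 2)
    for c, dcol in zip(cols, per_col):
        d = int(round(dcol))
        if d > 0:
            mask[crest_top : crest_top + d, c] = True
    return mask


def lesion_bbox(spec: PhantomSpec) -> tuple[int, int, int, int] | None:
    """(row0, row1, col0, col1), half-open, bounding the declared lesion."""
    mask = lesion_mask(spec)
    if not mask.any():
        return None
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    return int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1


def generate_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render the phantom as a float image with values in [0, 255].

    Construction order: piecewise-constant structure (background, teeth,
    crest band in the gaps, lesion), then Gaussian blur, then additive
    Gaussian noise, then clipping. Identical spec implies a bit-identical
    array.
    """
    teeth, gaps, (crest_top, crest_h), (row_top, row_bot) = _geometry(spec)
    img = np.full((spec.height, spec.width), LEVELS["background"])
    for c0, c1 in teeth:
        img[row_top:row_bot, c0:c1] = LEVELS["tooth"]
    for g0, g1 in gaps:
        img[crest_top : crest_top + crest_h, g0:g1] = LEVELS["crest"]
    img[lesion_mask(spec)] = LEVELS["lesion"]
    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 255.0)


def degrade(image: np.ndarray, factor: float, method: str = "area") -> np.ndarray:
    """Downscale by ``factor`` (> 1); output dims = round(original / factor).

    The default ``area`` method is the neutral area-average downscaler,
    deliberately distinct from the upscaling kernels under evaluation; any
    resampling kernel name is also accepted.
    """
    if factor <= 1:
        raise ValueError("degrade factor must be > 1")
    image = np.asarray(image, dtype=float)
    oh = int(round(image.shape[0] / factor))
    ow = int(round(image.shape[1] / factor))
    if oh < 1 or ow < 1:
        raise ValueError("degrade factor leaves no pixels")
    if method == "area":
        return resize_area(image, oh, ow)
    return resize(image, oh, ow, kind=method)


# ---------------------------------------------------------------------------
# Observer rating simulator (cumulative-threshold ordinal model)
# ---------------------------------------------------------------------------

DEFAULT_METHOD_ORDER = ("nearest", "bilinear", "bicubic", "lanczos", "srcnn", "srgan")


@dataclass(frozen=True)
class ObserverModel:
    """Latent-quality rating model.

    ``method_quality`` places each method on an arbitrary latent scale;
    ``observer_bias`` shifts individual observers; ``thresholds`` are three
    strictly increasing cut points mapping the latent value to MOS 1-4.
    """

    method_quality: dict[str, float]
    observer_bias: dict[str, float] = field(default_factory=dict)
    observer_noise_sd: float = 1.0
    thresholds: tuple[float, float, float] = (0.0, 0.75, 1.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.method_quality:
            raise ValueError("method_quality must not be empty")
        if self.observer_noise_sd <= 0:
            raise ValueError("observer_noise_sd must be > 0")
        t = self.thresholds
        if not (t[0] < t[1] < t[2]):
            raise ValueError("thresholds must be strictly increasing")


def default_observer_model(seed: int = 0) -> ObserverModel:
    """Latent qualities in the canonical order nearest < bilinear < bicubic
    < lanczos < srcnn < srgan, evenly spaced (0.3 latent units per step
    against unit observer noise)."""
    quality = {m: 0.3 * i for i, m in enumerate(DEFAULT_METHOD_ORDER)}
    return ObserverModel(method_quality=quality, seed=seed)


def simulate_study1(
    n_observers: int = 50,
    n_images: int = 20,
    seed: int = 0,
    model: ObserverModel | None = None,
    bias_sd: float = 0.3,
    expert_fraction: float = 0.25,
) -> pd.DataFrame:
    """Convenience wrapper: a full simulated observer study.

    Draws per-observer biases from N(0, ``bias_sd``), labels the first
    ``expert_fraction`` of observers as experts and the rest as lay, and
    rates ``n_images`` images under every method of ``model`` (default: the
    canonical six-method ordering)."""
    rng = np.random.default_rng(seed)
    base = model or default_observer_model(seed=seed)
    n_expert = max(int(round(expert_fraction * n_observers)), 1)
    observers = [
        (f"obs_{i:03d}", "expert" if i < n_expert else "lay")
        for i in range(n_observers)
    ]
    biases = {oid: float(rng.normal(0.0, bias_sd)) for oid, _ in observers}
    model = ObserverModel(
        method_quality=base.method_quality,
        observer_bias=biases,
        observer_noise_sd=base.observer_noise_sd,
        thresholds=base.thresholds,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    image_ids = [f"img_{j:03d}" for j in range(n_images)]
    return simulate_ratings(model, image_ids, observers)


def simulate_ratings(
    model: ObserverModel,
    image_ids: list,
    observers: list[tuple[str, str]],
) -> pd.DataFrame:
    """Complete rating table: one MOS score per (observer, image, method).

    ``observers`` is a list of (observer_id, group) with group ``expert`` or
    ``lay``. Score = 1 + number of thresholds below the latent sample.
    """
    if not observers:
        raise ValueError("observer list must not be empty")
    if not image_ids:
        raise ValueError("image_ids must not be empty")
    methods = list(model.method_quality)
    rng = np.random.default_rng(model.seed)
    thr = np.asarray(model.thresholds)
    rows = []
    for obs_id, group in observers:
        bias = model.observer_bias.get(obs_id, 0.0)
        for m in methods:
            latent = (
                model.method_quality[m]
                + bias
                + rng.normal(0.0, model.observer_noise_sd, size=len(image_ids))
            )
            scores = 1 + (latent[:, None] > thr[None, :]).sum(axis=1)
            for img, sc in zip(image_ids, scores):
                rows.append((obs_id, group, img, m, int(sc)))
    return pd.DataFrame(
        rows, columns=["observer_id", "group", "image_id", "method", "score"]
    )


# ---------------------------------------------------------------------------
# Classifier-score simulator (binormal)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassifierSimSpec:
    """Two-class score model: class means separated by ``separation_d``
    standard-deviation units; scores squashed monotonically into [0, 1],
    which leaves the ROC (and its AUC = Phi(d / sqrt(2))) unchanged."""

    n_pos: int = 52
    n_neg: int = 52
    separation_d: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("class counts must be >= 1")
        if self.separation_d < 0:
            raise ValueError("separation_d must be >= 0")


def simulate_classifier_scores(spec: ClassifierSimSpec) -> pd.DataFrame:
    """Prediction table with columns sample_id, label, score."""
    rng = np.random.default_rng(spec.seed)
    pos = rng.normal(spec.separation_d, 1.0, size=spec.n_pos)
    neg = rng.normal(0.0, 1.0, size=spec.n_neg)
    raw = np.concatenate([pos, neg])
    scores = 1.0 / (1.0 + np.exp(-raw))  # logistic squash, strictly monotone
    labels = ["PBL"] * spec.n_pos + ["healthy"] * spec.n_neg
    ids = [f"s{i:05d}" for i in range(len(labels))]
    return pd.DataFrame({"sample_id": ids, "label": labels, "score": scores})


# ---------------------------------------------------------------------------
# Plain-text/PNG I/O helpers
# ---------------------------------------------------------------------------


def save_png(image: np.ndarray, path: str | Path) -> None:
    """Write as 8-bit grayscale PNG (quantizing if needed)."""
    Image.fromarray(quantize_u8(image), mode="L").save(Path(path))


def load_png(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale image as float array in [0, 255]."""
    return np.asarray(Image.open(Path(path)).convert("L"), dtype=float)
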
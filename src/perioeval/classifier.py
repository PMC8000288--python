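"""Binary classifier evaluation for periodontal bone-loss (PBL) detection,
plus the dataset-preparation rules used upstream of the classifiers:
histogram equalization, flip augmentation, and leakage-free splitting.

Positive class is ``PBL``, negative is ``healthy``. Confusion matrices are
2x2 counts (tn, fp, fn, tp); metrics are returned both as floats and exact
``Fraction``s so printed 3-decimal values can be checked without rounding
drift. Scored predictions live in DataFrames with columns
``sample_id, label, score`` (score in [0, 1], larger = more PBL-like).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

__all__ = [
    "POSITIVE_LABEL",
    "NEGATIVE_LABEL",
    "ConfusionMatrix",
    "MetricReport",
    "confusion_metrics",
    "equalize_histogram",
    "SplitSpec",
    "augment",
    "split",
    "roc_pr_curves",
    "ROCPRResult",
]

POSITIVE_LABEL = "PBL"
NEGATIVE_LABEL = "healthy"


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with PBL positive. ``declared_n`` (if given) lets
    :attr:`consistent` flag matrices whose cells do not sum to the stated
    test-set size."""

    tn: int
    fp: int
    fn: int
    tp: int
    declared_n: int | None = None

    def __post_init__(self) -> None:
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.n == 0:
            raise ValueError("all-zero confusion matrix")

    @property
    def n(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    @property
    def consistent(self) -> bool:
        return self.declared_n is None or self.n == self.declared_n


@dataclass
class MetricReport:
    """Diagnostic ratios; ``None`` where the denominator is zero (reported
    as undefined, never as 0)."""

    sensitivity: float | None
    specificity: float | None
    precision: float | None
    npv: float | None
    accuracy: float
    exact: dict[str, Fraction | None] = field(default_factory=dict)


def _ratio(num: int, den: int) -> tuple[float | None, Fraction | None]:
    if den == 0:
        return None, None
    return num / den, Fraction(num, den)


def confusion_metrics(cm: ConfusionMatrix) -> MetricReport:
    """Sensitivity TP/(FN+TP), specificity TN/(FP+TN), precision TP/(FP+TP),
    NPV TN/(FN+TN), accuracy (TP+TN)/n."""
    sens, sens_f = _ratio(cm.tp, cm.fn + cm.tp)
    spec, spec_f = _ratio(cm.tn, cm.fp + cm.tn)
    prec, prec_f = _ratio(cm.tp, cm.fp + cm.tp)
    npv, npv_f = _ratio(cm.tn, cm.fn + cm.tn)
    acc, acc_f = _ratio(cm.tp + cm.tn, cm.n)
    return MetricReport(
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        npv=npv,
        accuracy=acc,
        exact={
            "sensitivity": sens_f,
            "specificity": spec_f,
            "precision": prec_f,
            "npv": npv_f,
            "accuracy": acc_f,
        },
    )


# ---------------------------------------------------------------------------
# Dataset preparation
# ---------------------------------------------------------------------------


def equalize_histogram(image: np.ndarray) -> np.ndarray:
    """Global histogram equalization of an 8-bit image.

    Each occupied gray level g maps to round(255 * cdf(g)) where cdf is the
    normalized cumulative histogram. Constant images are returned unchanged
    (their histogram is degenerate and equalization is a no-op by
    convention).
    """
    img = np.asarray(image)
    if img.min() < 0 or img.max() > 255:
        raise ValueError("expected an 8-bit image with values in [0, 255]")
    levels = np.round(img).astype(int)
    if levels.min() == levels.max():
        return img.astype(float).copy()
    hist = np.bincount(levels.ravel(), minlength=256)
    cdf = np.cumsum(hist) / levels.size
    lut = np.rint(255.0 * cdf)
    return lut[levels].astype(float)


@dataclass
class SplitSpec:
    """Test quota, train/val ratio and per-class augmentation ops.

    Augmentation mirrors the class-balance motivation of the original
    design: the under-represented PBL class is doubled with horizontal
    flips, healthy regions get horizontal and vertical flips.
    """

    test_per_class: int = 52
    train_fraction: float = 0.8
    augment_ops: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            POSITIVE_LABEL: ("hflip",),
            NEGATIVE_LABEL: ("hflip", "vflip"),
        }
    )
    seed: int = 0


_FLIPS = {"hflip": lambda a: a[:, ::-1], "vflip": lambda a: a[::-1, :]}


def augment(
    samples: list[tuple[str, str, np.ndarray]],
    spec: SplitSpec | None = None,
) -> list[tuple[str, str, np.ndarray, str]]:
    """Expand each (sample_id, label, image) into original + flipped copies.

    Returns (sample_id, label, image, op) with ``op`` in
    {"original", "hflip", "vflip"} recording provenance; every output keeps
    its source's sample_id.
    """
    spec = spec or SplitSpec()
    out = []
    for sample_id, label, img in samples:
        if label not in spec.augment_ops:
            raise ValueError(f"unknown label {label!r}")
        img = np.asarray(img)
        out.append((sample_id, label, img, "original"))
        for op in spec.augment_ops[label]:
            out.append((sample_id, label, _FLIPS[op](img), op))
    return out


def split(
    samples: list[tuple[str, str, np.ndarray]],
    spec: SplitSpec | None = None,
) -> dict[str, list[tuple[str, str, np.ndarray, str]]]:
    """Partition into test / train / val without leakage.

    ``test_per_class`` originals per class are drawn first (never
    augmented); the remaining originals are split 80:20 at the original
    level and only then augmented, so a source image and its flips always
    land in the same partition. Deterministic given ``spec.seed``.
    """
    spec = spec or SplitSpec()
    rng = np.random.default_rng(spec.seed)
    by_label: dict[str, list] = {}
    seen = set()
    for s in samples:
        if s[0] in seen:
            raise ValueError(f"duplicate sample_id {s[0]!r}")
        seen.add(s[0])
        by_label.setdefault(s[1], []).append(s)
    parts: dict[str, list] = {"train": [], "val": [], "test": []}
    for label, items in by_label.items():
        if len(items) < spec.test_per_class:
            raise ValueError(
                f"class {label!r} has {len(items)} originals, "
                f"test quota is {spec.test_per_class}"
            )
        order = rng.permutation(len(items))
        test_items = [items[i] for i in order[: spec.test_per_class]]
        rest = [items[i] for i in order[spec.test_per_class :]]
        parts["test"].extend(
            (sid, lab, img, "original") for sid, lab, img in test_items
        )
        n_train = int(round(spec.train_fraction * len(rest)))
        parts["train"].extend(augment(rest[:n_train], spec))
        parts["val"].extend(augment(rest[n_train:], spec))
    return parts


# ---------------------------------------------------------------------------
# ROC / PR curves
# ---------------------------------------------------------------------------


@dataclass
class ROCPRResult:
    fpr: np.ndarray
    tpr: np.ndarray
    recall: np.ndarray
    precision: np.ndarray
    thresholds: np.ndarray
    auc_roc: float
    auc_pr: float
    pr_convention: str = "step"  # precision held at each recall step


def validate_predictions(preds: pd.DataFrame) -> pd.DataFrame:
    for c in ("sample_id", "label", "score"):
        if c not in preds.columns:
            raise ValueError(f"prediction table missing column {c!r}")
    bad = set(preds["label"]) - {POSITIVE_LABEL, NEGATIVE_LABEL}
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    if ((preds["score"] < 0) | (preds["score"] > 1)).any():
        raise ValueError("scores must lie in [0, 1]")
    return preds


def roc_pr_curves(preds: pd.DataFrame) -> ROCPRResult:
    """Threshold sweep over the distinct scores (descending, ties grouped).

    ROC-AUC is the trapezoidal area, which under this tie handling equals
    the rank statistic P(score_pos > score_neg) + 0.5 P(equal). PR-AUC uses
    the step convention: the precision attained at each threshold is held
    over that threshold's recall increment.
    """
    validate_predictions(preds)
    y = (preds["label"] == POSITIVE_LABEL).to_numpy()
    s = preds["score"].to_numpy(dtype=float)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-s, kind="stable")
    y, s = y[order], s[order]
    # group tied scores: cumulative counts at each distinct-score boundary
    distinct = np.nonzero(np.diff(s))[0]
    idx = np.concatenate([distinct, [len(s) - 1]])
    tp = np.cumsum(y)[idx].astype(float)
    fp = np.cumsum(~y)[idx].astype(float)
    thresholds = s[idx]
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    auc_roc = float(np.trapezoid(tpr, fpr))
    recall = tp / n_pos
    precision = tp / (tp + fp)
    auc_pr = float(np.sum(np.diff(np.concatenate([[0.0], recall])) * precision))
    return ROCPRResult(
        fpr=fpr,
        tpr=tpr,
        recall=recall,
        precision=precision,
        thresholds=thresholds,
        auc_roc=auc_roc,
        auc_pr=auc_pr,
    )
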
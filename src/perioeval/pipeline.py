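"""End-to-end runs: the observer study (VGC + Wilcoxon), the classifier
study (confusion-matrix metrics + ROC/PR), and the degrade-then-restore
image-quality protocol. Each run writes CSV reports plus a JSON manifest
(config echo, seed, package version, config hash) sufficient to reproduce
it; all stages are deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classifier import ConfusionMatrix, confusion_metrics, roc_pr_curves
from .quality import downup_protocol
from .synthetic import PhantomSpec, generate_phantom
from .vgc import (
    score_distribution,
    validate_rating_table,
    vgc_curve,
    vgc_matrix,
    wilcoxon_one_sided,
)

__all__ = [
    "read_ratings_csv",
    "run_study1",
    "run_study2",
    "run_protocol",
]

log = logging.getLogger("perioeval")

_METRIC_KEYS = ("precision", "sensitivity", "specificity", "npv", "accuracy")


def _write_manifest(out_dir: Path, config: dict, seed: int | None) -> Path:
    payload = {
        "package": "perioeval",
        "version": __version__,
        "seed": seed,
        "config": config,
    }
    blob = json.dumps(payload, sort_keys=True, default=str)
    payload["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
    return path


def read_ratings_csv(path: str | Path) -> pd.DataFrame:
    """Read a rating table, reporting malformed rows with line numbers."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no rating rows")
    problems = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            score = int(row.get("score"))
        except (TypeError, ValueError):
            problems.append(f"line {line}: non-integer score {row.get('score')!r}")
            continue
        if score not in (1, 2, 3, 4):
            problems.append(f"line {line}: score {score} outside 1-4")
    if problems:
        raise ValueError(f"{path}: " + "; ".join(problems[:10]))
    return validate_rating_table(df)


def run_study1(
    ratings: pd.DataFrame,
    out_dir: str | Path,
    pairs: list[tuple[str, str]] | None = None,
    populations: list | None = None,
    seed: int | None = None,
    config: dict | None = None,
) -> dict:
    """Observer-study report bundle: score-count blocks per population, the
    AUC matrix, pairwise Wilcoxon tests over all observers, and curve point
    files."""
    t0 = time.perf_counter()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ratings = validate_rating_table(ratings)
    methods = list(dict.fromkeys(ratings["method"]))
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(methods) for b in methods[i + 1 :]]
    if populations is None:
        populations = ["experts", "lay", "all"]

    count_rows = []
    for pop in populations:
        for m in methods:
            dist = score_distribution(ratings, m, pop)
            for x, c in zip((1, 2, 3, 4), dist.counts):
                count_rows.append(
                    {"population": str(pop), "method": m, "score": x, "count": int(c)}
                )
    counts = pd.DataFrame(count_rows)
    counts.to_csv(out_dir / "score_counts.csv", index=False)

    auc = vgc_matrix(ratings, pairs=pairs, populations=populations)
    # reports carry 3 decimals (rounded once from full precision); the
    # returned frame keeps full precision
    auc.round(3).to_csv(out_dir / "vgc_auc.csv", index=False)

    point_rows = []
    for a, b in pairs:
        for pop in populations:
            curve = vgc_curve(
                score_distribution(ratings, a, pop),
                score_distribution(ratings, b, pop),
            )
            for k, (x, y) in enumerate(curve.points):
                point_rows.append(
                    {
                        "method_a": a,
                        "method_b": b,
                        "population": str(pop),
                        "point": k,
                        "x": x,
                        "y": y,
                    }
                )
    pd.DataFrame(point_rows).to_csv(out_dir / "vgc_curves.csv", index=False)

    wx_rows = []
    for a, b in pairs:
        res = wilcoxon_one_sided(ratings, a, b)
        wx_rows.append(
            {
                "method_a": a,
                "method_b": b,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "n_effective": res.n_effective,
                "exact": res.exact,
                "indeterminate": res.indeterminate,
            }
        )
    wilcoxon = pd.DataFrame(wx_rows)
    wilcoxon.to_csv(out_dir / "wilcoxon.csv", index=False)

    _write_manifest(
        out_dir,
        {"stage": "study1", "pairs": pairs, "populations": populations,
         "n_ratings": len(ratings), **(config or {})},
        seed,
    )
    log.info("study1 finished in %.2f s", time.perf_counter() - t0)
    return {"counts": counts, "auc": auc, "wilcoxon": wilcoxon, "out_dir": out_dir}


def run_study2(
    out_dir: str | Path,
    confusions: pd.DataFrame | None = None,
    predictions: pd.DataFrame | None = None,
    seed: int | None = None,
    config: dict | None = None,
) -> dict:
    """Classifier-study report bundle.

    ``confusions`` rows need columns model, tn, fp, fn, tp (optionally
    declared_n); matrices whose cells do not sum to declared_n are flagged
    ``consistent = False`` but still reported. ``predictions`` (sample_id,
    label, score) adds ROC/PR curves and their AUCs.
    """
    t0 = time.perf_counter()
    if confusions is None and predictions is None:
        raise ValueError("need a confusion table and/or a prediction table")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    metrics = None
    if confusions is not None:
        rows = []
        for r in confusions.itertuples():
            cm = ConfusionMatrix(
                tn=int(r.tn), fp=int(r.fp), fn=int(r.fn), tp=int(r.tp),
                declared_n=int(getattr(r, "declared_n", r.tn + r.fp + r.fn + r.tp)),
            )
            if not cm.consistent:
                log.warning(
                    "model %s: confusion cells sum to %d, declared n = %d",
                    r.model, cm.n, cm.declared_n,
                )
            rep = confusion_metrics(cm)
            rows.append(
                {
                    "model": r.model,
                    "n": cm.n,
                    "consistent": cm.consistent,
                    **{k: getattr(rep, k) for k in _METRIC_KEYS},
                }
            )
        metrics = pd.DataFrame(rows)
        metrics.to_csv(out_dir / "classifier_metrics.csv", index=False)
    curves = None
    if predictions is not None:
        res = roc_pr_curves(predictions)
        curves = res
        pd.DataFrame({"fpr": res.fpr, "tpr": res.tpr}).to_csv(
            out_dir / "roc_curve.csv", index=False
        )
        pd.DataFrame({"recall": res.recall, "precision": res.precision}).to_csv(
            out_dir / "pr_curve.csv", index=False
        )
        (out_dir / "curve_auc.json").write_text(
            json.dumps(
                {"auc_roc": res.auc_roc, "auc_pr": res.auc_pr,
                 "pr_convention": res.pr_convention}
            )
        )
    _write_manifest(out_dir, {"stage": "study2", **(config or {})}, seed)
    log.info("study2 finished in %.2f s", time.perf_counter() - t0)
    return {"metrics": metrics, "curves": curves, "out_dir": out_dir}


def run_protocol(
    out_dir: str | Path,
    images: list[np.ndarray] | None = None,
    n_phantoms: int = 5,
    methods: list[str] | None = None,
    size: int = 720,
    low: int = 128,
    seed: int = 0,
    config: dict | None = None,
) -> dict:
    """Degrade-then-restore IQM report over supplied images or phantoms."""
    t0 = time.perf_counter()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    methods = methods or ["nearest", "bilinear", "bicubic", "lanczos"]
    if images is None:
        images = [
            generate_phantom(
                PhantomSpec(height=size, width=size, n_teeth=3 + i % 2,
                            lesion="crater" if i % 2 else "none",
                            seed=seed + i)
            )
            for i in range(n_phantoms)
        ]
    for i, img in enumerate(images):
        if np.asarray(img).shape != (size, size):
            raise ValueError(f"image {i}: shape {np.asarray(img).shape} != ({size}, {size})")
    report = downup_protocol(images, methods, size=size, low=low)
    report.table.to_csv(out_dir / "iqm_report.csv", index=False)
    report.per_image.to_csv(out_dir / "iqm_per_image.csv", index=False)
    _write_manifest(
        out_dir,
        {"stage": "protocol", "methods": methods, "size": size, "low": low,
         "n_images": len(images), **(config or {})},
        seed,
    )
    log.info("protocol finished in %.2f s", time.perf_counter() - t0)
    return {"report": report, "out_dir": out_dir}
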
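"""Bundled observer-study and classifier-study fixtures.

Two small CSVs ship with the package so the full evaluation pipeline runs
offline:

``study1_mos_counts.csv``
    MOS score counts per population block (each of five experts, the pooled
    expert block, the pooled lay block of 17 participants, and the pooled
    all-observers block) for the six resolution-improvement methods over
    five rated radiographs. Note one transcription-faithful quirk of the
    source tables: expert 3's lanczos column sums to 6 ratings over 5
    images, and consequently the per-expert blocks do not add up to the
    pooled expert block for that one method. Group-level analysis uses the
    pooled blocks, which are internally consistent (experts 25, lay 85,
    all 110 ratings per method).

``study2_confusions.csv``
    2x2 confusion matrices for the twelve CNN classifiers (two
    architectures x six pre-processing methods) on a declared 104-sample
    test set. One matrix (Inception_Bilinear) does not sum to 104; it is
    kept verbatim and flagged downstream.
"""

from __future__ import annotations

from importlib.resources import files

import numpy as np
import pandas as pd

from .classifier import ConfusionMatrix

__all__ = [
    "METHODS",
    "METHOD_PAIRS",
    "study1_count_blocks",
    "load_study1_ratings",
    "load_study2_confusions",
    "study2_confusion_matrices",
]

METHODS = ("nearest", "bilinear", "bicubic", "lanczos", "srcnn", "srgan")

#: the 15 ordered method pairs of the observer study (A = x-axis, B = y-axis)
METHOD_PAIRS = tuple(
    (a, b) for i, a in enumerate(METHODS) for b in METHODS[i + 1 :]
)


def _data_path(name: str):
    return files("perioeval").joinpath("data", name)


def study1_count_blocks() -> pd.DataFrame:
    """Raw count blocks: population, group, method, score, count."""
    with _data_path("study1_mos_counts.csv").open() as f:
        return pd.read_csv(f)


def load_study1_ratings() -> pd.DataFrame:
    """Pooled-group rating table expanded to one row per rating.

    The pooled expert block (25 ratings per method) and pooled lay block
    (85 per method) are expanded under pseudo observer ids ``experts_pool``
    and ``lay_pool``. Image ids are synthetic and sequential — counts fully
    determine every VGC quantity, and the original per-image assignment is
    not recoverable from published counts — so paired per-image statistics
    on this table reflect an arbitrary pairing.
    """
    blocks = study1_count_blocks()
    rows = []
    for pop, obs_id, group in (
        ("experts_all", "experts_pool", "expert"),
        ("lay_all", "lay_pool", "lay"),
    ):
        sub = blocks[blocks["population"] == pop]
        for method in METHODS:
            scores = np.repeat(
                sub.loc[sub["method"] == method, "score"].to_numpy(),
                sub.loc[sub["method"] == method, "count"].to_numpy(),
            )
            for k, s in enumerate(sorted(scores)):
                rows.append((obs_id, group, f"img_{k:03d}", method, int(s)))
    return pd.DataFrame(
        rows, columns=["observer_id", "group", "image_id", "method", "score"]
    )


def load_study2_confusions() -> pd.DataFrame:
    with _data_path("study2_confusions.csv").open() as f:
        return pd.read_csv(f)


def study2_confusion_matrices() -> dict[str, ConfusionMatrix]:
    """Confusion matrices keyed by model name, with declared n attached."""
    df = load_study2_confusions()
    return {
        r.model: ConfusionMatrix(
            tn=int(r.tn), fp=int(r.fp), fn=int(r.fn), tp=int(r.tp),
            declared_n=int(r.declared_n),
        )
        for r in df.itertuples()
    }
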
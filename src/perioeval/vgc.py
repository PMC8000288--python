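"""Visual grading characteristics (VGC) analysis of ordinal quality ratings.

Observers score images processed by competing methods on a 4-level mean
opinion score (MOS) scale (1 = poor ... 4 = very high). For a method M and
an observer population, the score counts define a probability distribution
P(x) and a top-down cumulative C(x) = P(score >= x) for x = 4, 3, 2, 1.
The VGC curve comparing methods A (x-axis) and B (y-axis) is the polyline
through (0, 0) followed by (C_A(x), C_B(x)) for x = 4, 3, 2, 1; its
trapezoidal area is the VGC AUC. AUC > 0.5 means B's ratings stochastically
dominate A's (B is rated better); self-comparison gives exactly 0.5 and
AUC(A, B) = 1 - AUC(B, A).

Rating tables are pandas DataFrames with columns
``observer_id, group, image_id, method, score`` where ``group`` is
``expert`` or ``lay`` and scores are integers on the declared scale.
A paired one-sided Wilcoxon signed-rank test over (observer, image) units
complements the AUC with a significance statement.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SCALE",
    "RATING_COLUMNS",
    "ScoreDistribution",
    "score_distribution",
    "cumulative_top_down",
    "VGCCurve",
    "vgc_curve",
    "vgc_auc",
    "vgc_matrix",
    "WilcoxonResult",
    "wilcoxon_one_sided",
    "validate_rating_table",
]

SCALE = (1, 2, 3, 4)
RATING_COLUMNS = ("observer_id", "group", "image_id", "method", "score")
GROUPS = ("expert", "lay")


def validate_rating_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check schema, score range and (observer, image, method) uniqueness."""
    missing = [c for c in RATING_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"rating table missing columns: {missing}")
    bad = set(table["score"]) - set(SCALE)
    if bad:
        raise ValueError(f"scores outside the {SCALE} scale: {sorted(bad)}")
    bad_group = set(table["group"]) - set(GROUPS)
    if bad_group:
        raise ValueError(f"unknown observer groups: {sorted(bad_group)}")
    key = ["observer_id", "image_id", "method"]
    if table.duplicated(subset=key).any():
        raise ValueError("duplicate (observer, image, method) rows")
    return table


@dataclass
class ScoreDistribution:
    """Score counts and probabilities for one method and population."""

    method: str
    counts: np.ndarray  # length 4, counts for scores 1..4
    population: str = "all"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(SCALE),):
            raise ValueError("counts must have one entry per score level")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if self.counts.sum() == 0:
            raise ValueError("empty distribution")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        """P(x) for x = 1..4."""
        return self.counts / self.counts.sum()

    @classmethod
    def from_counts(cls, method: str, counts, population: str = "all"):
        return cls(method=method, counts=np.asarray(counts), population=population)


def _population_mask(table: pd.DataFrame, population) -> pd.Series:
    if population in (None, "all"):
        return pd.Series(True, index=table.index)
    if population in ("experts", "expert", "experts-all"):
        return table["group"] == "expert"
    if population in ("lay", "lay-all"):
        return table["group"] == "lay"
    return table["observer_id"] == population  # single observer


def score_distribution(
    table: pd.DataFrame, method: str, population="all"
) -> ScoreDistribution:
    """Count-based score distribution for ``method`` over a population.

    ``population`` is ``"all"``, ``"experts"``, ``"lay"``, or an observer id.
    """
    sel = table[(table["method"] == method) & _population_mask(table, population)]
    if sel.empty:
        raise ValueError(f"no ratings for method={method!r}, population={population!r}")
    counts = np.array([(sel["score"] == x).sum() for x in SCALE])
    label = population if isinstance(population, str) else str(population)
    return ScoreDistribution(method=method, counts=counts, population=label)


def cumulative_top_down(dist: ScoreDistribution) -> np.ndarray:
    """C(x) = P(score >= x) evaluated at x = 4, 3, 2, 1 (in that order).

    The last entry is exactly 1 (total probability mass).
    """
    p = dist.probabilities
    return np.array([p[3], p[3] + p[2], p[3] + p[2] + p[1], 1.0])


@dataclass
class VGCCurve:
    """Polyline (0,0) -> (C_A(4), C_B(4)) -> ... -> (C_A(1), C_B(1)) = (1,1)."""

    method_a: str
    method_b: str
    points: np.ndarray = field(repr=False)  # (5, 2)
    auc: float = 0.0


def vgc_curve(dist_a: ScoreDistribution, dist_b: ScoreDistribution) -> VGCCurve:
    """VGC curve for method A on the x-axis vs method B on the y-axis."""
    ca = cumulative_top_down(dist_a)
    cb = cumulative_top_down(dist_b)
    points = np.column_stack(
        [np.concatenate([[0.0], ca]), np.concatenate([[0.0], cb])]
    )
    curve = VGCCurve(method_a=dist_a.method, method_b=dist_b.method, points=points)
    curve.auc = vgc_auc(curve)
    return curve


def vgc_auc(curve: VGCCurve) -> float:
    """Trapezoidal area under the curve's polyline; in [0, 1]."""
    x = curve.points[:, 0]
    y = curve.points[:, 1]
    if (np.diff(x) < -1e-12).any() or (np.diff(y) < -1e-12).any():
        raise ValueError("curve points must be nondecreasing in both coordinates")
    return float(np.trapezoid(y, x))


def vgc_matrix(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    populations: list | None = None,
) -> pd.DataFrame:
    """AUC for each (method pair, population), wide format.

    Default pairs are all ordered pairs (A earlier than B) over the methods
    present, in first-appearance order; default populations are every
    individual expert, ``experts``, ``lay`` and ``all`` (group populations
    pool their members' ratings into one count table).
    """
    methods = list(dict.fromkeys(table["method"]))
    if pairs is None:
        pairs = [
            (a, b) for i, a in enumerate(methods) for b in methods[i + 1 :]
        ]
    for a, b in pairs:
        for m in (a, b):
            if m not in methods:
                raise ValueError(f"method {m!r} not present in the rating table")
    if populations is None:
        experts = sorted(table.loc[table["group"] == "expert", "observer_id"].unique())
        populations = experts + ["experts", "lay", "all"]
    rows = []
    for a, b in pairs:
        row = {"method_a": a, "method_b": b}
        for pop in populations:
            da = score_distribution(table, a, pop)
            db = score_distribution(table, b, pop)
            row[str(pop)] = vgc_curve(da, db).auc
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Paired one-sided Wilcoxon signed-rank test
# ---------------------------------------------------------------------------


@dataclass
class WilcoxonResult:
    statistic: float  # W+ = rank sum of positive differences
    p_value: float | None
    n_effective: int  # pairs remaining after dropping zero differences
    exact: bool
    indeterminate: bool = False


def _wilcoxon_exact_p(ranks: np.ndarray, w_obs: float) -> float:
    """P(W+ >= w_obs) by enumerating all sign assignments of the ranks."""
    n = len(ranks)
    count = 0
    for signs in itertools.product((0.0, 1.0), repeat=n):
        if float(np.dot(signs, ranks)) >= w_obs - 1e-9:
            count += 1
    return count / 2**n


def wilcoxon_one_sided(
    table: pd.DataFrame,
    method_a: str,
    method_b: str,
    exact_max_n: int = 12,
) -> WilcoxonResult:
    """One-sided paired signed-rank test of H_A: B is rated higher than A.

    Pairing units are (observer, image); zero differences are dropped, tied
    absolute differences receive mid-ranks. The null distribution is
    enumerated exactly for effective n <= ``exact_max_n``; otherwise a
    tie-corrected normal approximation with continuity correction is used.
    If every difference is zero the test is indeterminate.
    """
    key = ["observer_id", "image_id"]
    a = table[table["method"] == method_a].set_index(key)["score"]
    b = table[table["method"] == method_b].set_index(key)["score"]
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("no (observer, image) pairs scored under both methods")
    d = (b.loc[common] - a.loc[common]).to_numpy(dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(
            statistic=float("nan"), p_value=None, n_effective=0, exact=True,
            indeterminate=True,
        )
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        p = _wilcoxon_exact_p(ranks, w_plus)
        return WilcoxonResult(w_plus, p, n, exact=True)
    mu = n * (n + 1) / 4.0
    # tie correction: subtract sum(t^3 - t)/48 from the no-tie variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts**3 - tie_counts).sum()) / 48.0
    z = (w_plus - mu - 0.5) / np.sqrt(var)
    return WilcoxonResult(w_plus, float(stats.norm.sf(z)), n, exact=False)
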
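"""VGC distributions, curves, AUC properties and the paired Wilcoxon test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from perioeval.datasets import load_study1_ratings
from perioeval.vgc import (
    ScoreDistribution,
    cumulative_top_down,
    score_distribution,
    validate_rating_table,
    vgc_auc,
    vgc_curve,
    vgc_matrix,
    wilcoxon_one_sided,
)

counts_strategy = st.lists(
    st.integers(min_value=0, max_value=30), min_size=4, max_size=4
).filter(lambda c: sum(c) > 0)


def _table_from_diffs(diffs):
    """Rating-like table realizing given per-pair score differences."""
    rows = []
    for i, d in enumerate(diffs):
        a = 2
        b = a + d
        rows.append((f"o{i}", "expert", "img", "A", int(a)))
        rows.append((f"o{i}", "expert", "img", "B", int(b)))
    return pd.DataFrame(
        rows, columns=["observer_id", "group", "image_id", "method", "score"]
    )


def fine_grid_auc(points, subdivisions=2000):
    """Midpoint-rule integration of the piecewise-linear curve, segment by
    segment — independent of the trapezoid formula."""
    total = 0.0
    for (x0, y0), (x1, y1) in zip(points[:-1], points[1:]):
        u = (np.arange(subdivisions) + 0.5) / subdivisions
        ym = y0 + (y1 - y0) * u
        total += float(np.sum(ym) * (x1 - x0) / subdivisions)
    return total


class TestScoreDistribution:
    def test_worked_example_observer1_bicubic(self):
        # observer rated five images {1,1,1,2,2}
        rows = [("e1", "expert", f"i{k}", "bicubic", s)
                for k, s in enumerate([1, 1, 1, 2, 2])]
        t = pd.DataFrame(rows, columns=["observer_id", "group", "image_id",
                                        "method", "score"])
        dist = score_distribution(t, "bicubic", "e1")
        np.testing.assert_allclose(dist.probabilities, [0.6, 0.4, 0.0, 0.0])
        np.testing.assert_allclose(cumulative_top_down(dist), [0.0, 0.0, 0.4, 1.0])

    def test_experts_nearest_counts_from_fixture(self):
        t = load_study1_ratings()
        dist = score_distribution(t, "nearest", "experts")
        np.testing.assert_array_equal(dist.counts, [9, 6, 8, 2])
        np.testing.assert_allclose(dist.probabilities, [0.36, 0.24, 0.32, 0.08])

    def test_point_mass(self):
        dist = ScoreDistribution.from_counts("m", [0, 0, 5, 0])
        np.testing.assert_allclose(dist.probabilities, [0, 0, 1, 0])
        np.testing.assert_allclose(cumulative_top_down(dist), [0, 1, 1, 1])

    def test_uniform_cumulative(self):
        dist = ScoreDistribution.from_counts("m", [1, 1, 1, 1])
        np.testing.assert_allclose(cumulative_top_down(dist),
                                   [0.25, 0.5, 0.75, 1.0])

    def test_empty_selection_rejected(self, tiny_rating_table):
        with pytest.raises(ValueError):
            score_distribution(tiny_rating_table, "Z")

    def test_invalid_tables_rejected(self, tiny_rating_table):
        bad = tiny_rating_table.copy()
        bad.loc[0, "score"] = 7
        with pytest.raises(ValueError):
            validate_rating_table(bad)
        dup = pd.concat([tiny_rating_table, tiny_rating_table.iloc[[0]]])
        with pytest.raises(ValueError):
            validate_rating_table(dup)


class TestVGCCurve:
    def test_experts_nearest_bilinear_points(self):
        t = load_study1_ratings()
        curve = vgc_curve(
            score_distribution(t, "nearest", "experts"),
            score_distribution(t, "bilinear", "experts"),
        )
        want = np.array(
            [[0, 0], [0.08, 0.08], [0.40, 0.32], [0.64, 0.56], [1, 1]]
        )
        np.testing.assert_allclose(curve.points, want, atol=1e-12)
        assert curve.auc == pytest.approx(0.454, abs=5e-4)

    def test_self_comparison_on_diagonal(self):
        dist = ScoreDistribution.from_counts("m", [3, 1, 4, 1])
        curve = vgc_curve(dist, dist)
        np.testing.assert_allclose(curve.points[:, 0], curve.points[:, 1])
        assert curve.auc == pytest.approx(0.5, abs=1e-15)

    def test_dominating_distribution_curve_above_diagonal(self):
        lo = ScoreDistribution.from_counts("lo", [4, 3, 2, 1])
        hi = ScoreDistribution.from_counts("hi", [1, 2, 3, 4])
        curve = vgc_curve(lo, hi)
        assert (curve.points[:, 1] >= curve.points[:, 0] - 1e-12).all()
        assert curve.auc > 0.5

    @given(a=counts_strategy, b=counts_strategy)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_complement_symmetry_and_oracle(self, a, b):
        da = ScoreDistribution.from_counts("A", a)
        db = ScoreDistribution.from_counts("B", b)
        ab = vgc_curve(da, db)
        ba = vgc_curve(db, da)
        assert ab.auc + ba.auc == pytest.approx(1.0, abs=1e-12)
        assert ab.auc == pytest.approx(fine_grid_auc(ab.points), abs=1e-12)
        assert 0.0 <= ab.auc <= 1.0

    def test_monotone_response_moving_mass_up(self, rng):
        da = ScoreDistribution.from_counts("A", [5, 5, 5, 5])
        for _ in range(50):
            counts = rng.integers(0, 10, size=4)
            lower = int(rng.integers(0, 3))
            upper = int(rng.integers(lower + 1, 4))
            counts[lower] += 1  # ensure movable mass and nonzero total
            moved = counts.copy()
            moved[lower] -= 1
            moved[upper] += 1
            auc0 = vgc_curve(da, ScoreDistribution.from_counts("B", counts)).auc
            auc1 = vgc_curve(da, ScoreDistribution.from_counts("B", moved)).auc
            assert auc1 >= auc0 - 1e-12

    def test_unordered_points_rejected(self):
        from perioeval.vgc import VGCCurve

        bad = VGCCurve("a", "b", np.array([[0, 0], [0.5, 0.4], [0.3, 1.0], [1, 1]]))
        with pytest.raises(ValueError):
            vgc_auc(bad)


class TestVGCMatrix:
    def test_pair_auc_complement_over_fixture(self):
        t = load_study1_ratings()
        m_ab = vgc_matrix(t, pairs=[("nearest", "srgan")], populations=["all"])
        m_ba = vgc_matrix(t, pairs=[("srgan", "nearest")], populations=["all"])
        assert m_ab["all"][0] + m_ba["all"][0] == pytest.approx(1.0, abs=1e-12)

    def test_self_pair_gives_half(self, tiny_rating_table):
        m = vgc_matrix(tiny_rating_table, pairs=[("A", "A")], populations=["all"])
        assert m["all"][0] == pytest.approx(0.5)

    def test_missing_method_rejected(self, tiny_rating_table):
        with pytest.raises(ValueError):
            vgc_matrix(tiny_rating_table, pairs=[("A", "Z")])


class TestWilcoxon:
    def test_three_positive_pairs_exact_eighth(self):
        res = wilcoxon_one_sided(_table_from_diffs([1, 1, 1]), "A", "B")
        assert res.exact
        assert res.p_value == pytest.approx(0.125)

    def test_all_zero_differences_indeterminate(self):
        res = wilcoxon_one_sided(_table_from_diffs([0, 0, 0]), "A", "B")
        assert res.indeterminate
        assert res.p_value is None

    def test_tied_differences_against_binomial_closed_form(self):
        # 7 positive and 1 negative unit differences: all ranks tie at 4.5,
        # so W+ >= obs iff at least 7 of 8 signs are positive
        res = wilcoxon_one_sided(_table_from_diffs([1] * 7 + [-1]), "A", "B")
        assert res.p_value == pytest.approx(9 / 256)

    @pytest.mark.parametrize("n", [4, 6, 8, 10])
    def test_matches_exhaustive_enumeration(self, n, rng):
        diffs = rng.choice([-2, -1, 1, 2], size=n)
        while (diffs > 0).sum() == 0:
            diffs = rng.choice([-2, -1, 1, 2], size=n)
        res = wilcoxon_one_sided(_table_from_diffs(diffs), "A", "B")
        ranks = stats.rankdata(np.abs(diffs))
        w_obs = ranks[diffs > 0].sum()
        count = sum(
            1
            for signs in itertools.product([0, 1], repeat=n)
            if np.dot(signs, ranks) >= w_obs - 1e-9
        )
        assert res.p_value == pytest.approx(count / 2**n)

    def test_tie_free_exact_matches_scipy(self):
        # distinct |d| magnitudes (tie-free) so scipy's exact mode applies;
        # these exceed the 1-4 scale, so the enumerator is checked directly
        rng = np.random.default_rng(5)
        diffs = rng.permutation(np.arange(1, 11)) * rng.choice([-1, 1], size=10)
        want = stats.wilcoxon(
            diffs.astype(float), alternative="greater", method="exact"
        ).pvalue
        from perioeval.vgc import _wilcoxon_exact_p

        ranks = stats.rankdata(np.abs(diffs))
        w_obs = ranks[diffs > 0].sum()
        assert _wilcoxon_exact_p(ranks, w_obs) == pytest.approx(want)

    def test_large_n_normal_approximation_close_to_exact(self, rng):
        diffs = rng.choice([-3, -1, 1, 2, 3], size=14, p=[0.1, 0.15, 0.3, 0.25, 0.2])
        table = _table_from_diffs(np.clip(diffs, -1, 2))
        exact = wilcoxon_one_sided(table, "A", "B", exact_max_n=20)
        approx = wilcoxon_one_sided(table, "A", "B", exact_max_n=5)
        assert exact.exact and not approx.exact
        assert approx.p_value == pytest.approx(exact.p_value, abs=0.02)

    def test_no_common_pairs_rejected(self):
        rows = [("o1", "expert", "i1", "A", 1), ("o2", "expert", "i2", "B", 2)]
        t = pd.DataFrame(rows, columns=["observer_id", "group", "image_id",
                                        "method", "score"])
        with pytest.raises(ValueError):
            wilcoxon_one_sided(t, "A", "B")
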
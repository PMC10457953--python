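import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import tomatoq as tq
from tomatoq.evaluate import DegenerateIndicatorError


def _imatrix(values, directions=None, groups=None):
    return tq.IndicatorMatrix(
        values=pd.DataFrame(values), directions=directions, groups=groups
    )


class TestMembership:
    @pytest.mark.parametrize(
        "x, direction, expected",
        [(0.0, "positive", 0.0), (10.0, "positive", 1.0), (0.0, "negative", 1.0),
         (10.0, "negative", 0.0), (5.0, "positive", 0.5), (5.0, "negative", 0.5)],
    )
    def test_endpoints_and_midpoint(self, x, direction, expected):
        assert tq.membership(x, 0.0, 10.0, direction) == expected

    def test_degenerate_indicator_signalled(self):
        with pytest.raises(DegenerateIndicatorError):
            tq.membership(3.0, 3.0, 3.0)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            tq.membership(11.0, 0.0, 10.0)

    @given(x=st.floats(0, 1), lo=st.floats(-5, 0), hi=st.floats(2, 5))
    def test_direction_reversal_complements(self, x, lo, hi):
        xv = lo + x * (hi - lo)
        pos = tq.membership(xv, lo, hi, "positive")
        neg = tq.membership(xv, lo, hi, "negative")
        assert pos + neg == pytest.approx(1.0)


class TestCompositeScores:
    def test_two_varieties_one_indicator(self):
        res = tq.composite_scores(_imatrix({"x": {"A": 1.0, "B": 3.0}}))
        assert res.composite.tolist() == [0.0, 1.0]
        assert res.rank.tolist() == [2, 1]

    def test_affine_invariance_of_columns(self):
        rng = np.random.default_rng(0)
        base = pd.DataFrame(
            rng.normal(size=(6, 4)), columns=list("wxyz"),
            index=[f"V{i}" for i in range(6)],
        )
        res1 = tq.composite_scores(_imatrix(base))
        scaled = base.copy()
        scaled["x"] = 3.5 * scaled["x"] + 11.0
        res2 = tq.composite_scores(_imatrix(scaled))
        assert np.allclose(res1.composite, res2.composite)
        assert res1.rank.equals(res2.rank)

    def test_negative_direction_flips_membership(self):
        values = {"x": {"A": 1.0, "B": 2.0, "C": 3.0}}
        pos = tq.composite_scores(_imatrix(values))
        neg = tq.composite_scores(_imatrix(values, directions={"x": "negative"}))
        assert np.allclose(neg.memberships["x"], 1.0 - pos.memberships["x"])

    def test_degenerate_indicator_excluded_and_counted(self, caplog):
        values = {"x": {"A": 1.0, "B": 3.0}, "flat": {"A": 2.0, "B": 2.0}}
        with caplog.at_level("WARNING"):
            res = tq.composite_scores(_imatrix(values))
        assert res.n_used == 1
        assert res.excluded == ("flat",)
        assert "flat" in caplog.text

    def test_all_degenerate_rejected(self):
        with pytest.raises(ValueError):
            tq.composite_scores(_imatrix({"flat": {"A": 1.0, "B": 1.0}}))

    def test_ranks_are_permutation_with_stable_ties(self):
        values = {"x": {"A": 2.0, "B": 2.0, "C": 1.0, "D": 3.0}}
        res = tq.composite_scores(_imatrix(values))
        assert sorted(res.rank) == [1, 2, 3, 4]
        # A and B tie; input order breaks the tie
        assert res.rank["A"] < res.rank["B"]


class TestGroupPercentDifference:
    def test_equal_means_zero(self):
        v = pd.Series([1.0, 1.0, 2.0, 2.0])
        g = pd.Series(["a", "b", "a", "b"])
        assert tq.group_percent_difference(v, g, "a", "b") == 0.0

    def test_zero_reference_rejected(self):
        v = pd.Series([1.0, 0.0])
        g = pd.Series(["a", "b"])
        with pytest.raises(ValueError):
            tq.group_percent_difference(v, g, "a", "b")

    def test_empty_group_rejected(self):
        v = pd.Series([1.0, 2.0])
        g = pd.Series(["a", "a"])
        with pytest.raises(ValueError):
            tq.group_percent_difference(v, g, "a", "b")


class TestPearson:
    def test_self_correlation(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 4.0, 3.0], "y": [0.0, 1.0, 2.0, 5.0]})
        res = tq.pearson_matrix(df)
        assert res.r.loc["x", "x"] == 1.0

    def test_anticorrelation(self):
        x = pd.Series([1.0, 2.0, 5.0, 3.0])
        res = tq.pearson_matrix(pd.DataFrame({"x": x, "neg": -x}))
        assert res.r.loc["x", "neg"] == pytest.approx(-1.0)

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(9, 5)), columns=list("abcde"))
        res = tq.pearson_matrix(df)
        n = len(df)
        for i in df.columns:
            for j in df.columns:
                x, y = df[i].to_numpy(), df[j].to_numpy()
                num = ((x - x.mean()) * (y - y.mean())).sum()
                den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
                r = num / den
                assert res.r.loc[i, j] == pytest.approx(r, rel=1e-10)
                if i != j:
                    t = r * np.sqrt((n - 2) / (1 - r**2))
                    p = 2 * stats.t.sf(abs(t), n - 2)
                    assert res.p.loc[i, j] == pytest.approx(p, rel=1e-10)

    def test_significance_stars_at_panel_size(self):
        # with n = 15, r = 0.60 crosses the 5% (not the 1%) threshold
        n, r = 15, 0.60
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2 * stats.t.sf(abs(t), n - 2)
        assert p < 0.05
        rng = np.random.default_rng(2)
        x = rng.normal(size=n)
        res = tq.pearson_matrix(pd.DataFrame({"x": x, "y": x + rng.normal(scale=1.1, size=n)}))
        observed = res.r.loc["x", "y"]
        expected_star = "**" if res.p.loc["x", "y"] < 0.01 else (
            "*" if res.p.loc["x", "y"] < 0.05 else ""
        )
        assert res.stars.loc["x", "y"] == expected_star
        assert -1 <= observed <= 1

    def test_constant_column_flagged_not_dropped(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
        res = tq.pearson_matrix(df)
        assert res.constant_columns == ("c",)
        assert np.isnan(res.r.loc["x", "c"])
        assert "c" in res.r.columns


class TestPCA:
    def test_exact_one_dimensional_structure(self):
        t = np.linspace(0, 1, 8)
        df = pd.DataFrame({"a": t, "b": 2 * t + 1, "c": -t})
        res = tq.pca(df)
        assert res.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_explained_fractions_sum_to_one(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(size=(10, 4)))
        res = tq.pca(df)
        assert res.explained_variance_fraction.sum() == pytest.approx(1.0)
        assert (np.diff(res.explained_variance_fraction) <= 1e-12).all()

    def test_reconstruction_with_all_components(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.normal(size=(7, 4)), columns=list("abcd"))
        res = tq.pca(df)
        Z = (df - df.mean()) / df.std(ddof=0)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(recon, Z.to_numpy(), atol=1e-10)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(rng.normal(size=(9, 5)))
        L = tq.pca(df).loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)

    def test_sign_convention(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(rng.normal(size=(9, 4)))
        L = tq.pca(df).loadings.to_numpy()
        for k in range(L.shape[1]):
            assert L[np.abs(L[:, k]).argmax(), k] > 0

    def test_zero_variance_column_named(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "flat": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="flat"):
            tq.pca(df)


class TestEllipse:
    def test_isotropic_cloud_nearly_circular(self):
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(4000, 2))
        e = tq.ellipse_95(pts)
        assert e.semi_axes[0] / e.semi_axes[1] == pytest.approx(1.0, abs=0.1)

    def test_collinear_points_degenerate(self):
        t = np.arange(5, dtype=float)
        pts = np.column_stack([t, 2 * t])
        e = tq.ellipse_95(pts)
        assert e.semi_axes[1] == pytest.approx(0.0, abs=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            tq.ellipse_95(np.zeros((2, 2)))

    def test_anisotropic_orientation(self):
        rng = np.random.default_rng(13)
        pts = rng.normal(size=(2000, 2)) * [5.0, 0.5]
        e = tq.ellipse_95(pts)
        assert abs(e.angle_deg) < 5 or abs(abs(e.angle_deg) - 180) < 5
        assert e.semi_axes[0] > 5 * e.semi_axes[1]
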
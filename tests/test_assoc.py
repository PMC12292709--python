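"""Association battery: correlations, BH, adjusted models, VIF, seasons."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.outliers_influence import variance_inflation_factor

from circalipid import (InsufficientDataError, ParticipantSeason,
                        ValidationError, bh_adjust, cohort_frame,
                        compare_seasons, fully_adjusted_model, generate_cohort,
                        linearize_circular, photoperiod_adjusted_model,
                        simple_correlations, vif)
from circalipid.synth import EffectSpec


def synthetic_frame(n=81, seed=0, beta=0.0):
    """Minimal analysis frame: one predictor, one outcome, demographics."""
    rng = np.random.default_rng(seed)
    photo = np.tile([1.0, 12.0, 23.0], n // 3 + 1)[:n]
    x = rng.normal(0, 1, n) + 0.1 * photo
    df = pd.DataFrame({
        "x": x,
        "photoperiod_h": photo,
        "age": rng.uniform(18, 59, n),
        "male": (rng.random(n) < 0.3).astype(float),
        "nn": (rng.random(n) < 0.6).astype(float),
    })
    df["y"] = beta * (x - x.mean()) / x.std(ddof=1) + rng.normal(0, 1, n)
    return df


class TestBH:
    def test_hand_step_up_case(self):
        flags = bh_adjust([0.001, 0.01, 0.02, 0.04, 0.2], fdr=0.1)
        assert flags.tolist() == [True, True, True, True, False]

    def test_edge_cases(self):
        assert not bh_adjust([0.9] * 5, fdr=0.1).any()
        assert bh_adjust([0.05], fdr=0.1).all()
        with pytest.raises(ValidationError):
            bh_adjust([])
        with pytest.raises(ValidationError):
            bh_adjust([-0.1, 0.5])
        with pytest.raises(ValidationError):
            bh_adjust([np.nan, 0.5])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_statsmodels(self, seed):
        p = np.random.default_rng(seed).uniform(0.001, 1, 30)
        ours = bh_adjust(p, fdr=0.1)
        ref = multipletests(p, alpha=0.1, method="fdr_bh")[0]
        assert (ours == ref).all()

    def test_null_false_flag_rate(self):
        """Over all-null vectors (m=14) the flag fraction stays within the
        FDR level plus Monte-Carlo margin."""
        rng = np.random.default_rng(42)
        flagged = [bh_adjust(rng.uniform(size=14), fdr=0.1).mean()
                   for _ in range(500)]
        mc_se = np.std(flagged, ddof=1) / np.sqrt(500)
        assert np.mean(flagged) <= 0.1 + 3 * mc_se


class TestSimpleCorrelations:
    def test_self_correlation_and_null(self):
        df = synthetic_frame(n=200, seed=1)
        df["y"] = df["x"]
        rows = simple_correlations(df, ["x"], ["y"])
        assert rows[0].estimate == pytest.approx(1.0)
        big = synthetic_frame(n=10_000, seed=2, beta=0.0)
        r = simple_correlations(big, ["x"], ["y"])[0].estimate
        assert abs(r) < 0.05

    def test_hand_computed_six_points(self):
        x = np.array([1, 2, 3, 4, 5, 6.0])
        y = np.array([2, 1, 4, 3, 7, 5.0])
        # covariance ratio computed by hand: r = Sxy / sqrt(Sxx*Syy)
        r_hand = (np.sum((x - x.mean()) * (y - y.mean()))
                  / np.sqrt(np.sum((x - x.mean()) ** 2)
                            * np.sum((y - y.mean()) ** 2)))
        df = pd.DataFrame({"x": x, "y": y})
        assert simple_correlations(df, ["x"], ["y"])[0].estimate == \
            pytest.approx(r_hand, abs=1e-12)

    def test_estimate_equals_standardized_slope(self):
        df = synthetic_frame(n=60, seed=3, beta=0.4)
        r = simple_correlations(df, ["x"], ["y"])[0].estimate
        xz = (df.x - df.x.mean()) / df.x.std(ddof=1)
        yz = (df.y - df.y.mean()) / df.y.std(ddof=1)
        slope = float(np.polyfit(xz, yz, 1)[0])
        assert r == pytest.approx(slope, abs=1e-10)

    def test_zero_variance_raises(self):
        df = pd.DataFrame({"x": [1.0] * 6, "y": [1, 2, 3, 4, 5, 6.0]})
        with pytest.raises(ValidationError):
            simple_correlations(df, ["x"], ["y"])


class TestAdjustedModels:
    def test_identity_outcome(self):
        df = synthetic_frame(n=60, seed=4)
        df["y"] = df["x"]
        row = photoperiod_adjusted_model(df, "y", "x")
        assert row.estimate == pytest.approx(1.0, abs=1e-9)
        assert row.variance_explained == pytest.approx(1.0, abs=1e-9)

    def test_six_row_design_matches_normal_equations(self):
        df = pd.DataFrame({
            "x": [0.0, 1, 2, 3, 4, 5],
            "photoperiod_h": [1.0, 12, 23, 1, 12, 23],
            "y": [1.0, 3, 2, 5, 4, 6],
        })
        row = photoperiod_adjusted_model(df, "y", "x")
        z = lambda v: (v - v.mean()) / v.std(ddof=1)
        X = np.column_stack([np.ones(6), z(df.x), z(df.photoperiod_h)])
        beta = np.linalg.solve(X.T @ X, X.T @ z(df.y))
        assert row.estimate == pytest.approx(beta[1], abs=1e-10)

    def test_type_one_error_rate(self):
        hits = 0
        reps = 1000
        for seed in range(reps):
            df = synthetic_frame(n=81, seed=seed, beta=0.0)
            hits += photoperiod_adjusted_model(df, "y", "x").p < 0.05
        assert 0.03 <= hits / reps <= 0.07

    def test_partial_eta2_matches_rss_difference_oracle(self):
        """Type III partial eta^2 == (RSS_red - RSS_full)/RSS_red via two
        explicit model fits, to 1e-10."""
        for seed in range(10):
            df = synthetic_frame(n=50, seed=seed, beta=0.3)
            row = fully_adjusted_model(df, "y", "x")
            z = lambda v: (np.asarray(v) - np.mean(v)) / np.std(v, ddof=1)
            y = z(df.y)
            full = np.column_stack([np.ones(50), z(df.x), z(df.photoperiod_h),
                                    z(df.age), z(df.male), z(df.nn)])
            red = full[:, [0, 2, 3, 4, 5]]
            rss = lambda X: float(np.sum((y - X @ np.linalg.lstsq(
                X, y, rcond=None)[0]) ** 2))
            rss_f, rss_r = rss(full), rss(red)
            oracle = (rss_r - rss_f) / rss_r
            assert row.variance_explained == pytest.approx(oracle, abs=1e-10)
            beta_oracle = np.linalg.lstsq(full, y, rcond=None)[0][1]
            assert row.estimate == pytest.approx(beta_oracle, abs=1e-10)

    def test_orthogonal_identity_gives_eta2_one(self):
        df = synthetic_frame(n=40, seed=12)
        df["y"] = df["x"]
        row = fully_adjusted_model(df, "y", "x")
        assert row.variance_explained == pytest.approx(1.0, abs=1e-6)

    def test_insufficient_rows_refused(self):
        df = synthetic_frame(n=6, seed=0)
        with pytest.raises(InsufficientDataError, match="insufficient df"):
            fully_adjusted_model(df, "y", "x")

    def test_sign_convention_earlier_acrophase_higher_hdl(self):
        """Planting 'earlier acrophase -> higher HDL-C' must report a
        negative acrophase beta."""
        eff = EffectSpec(effects={"hdl": {"ble_acrophase_h": -0.4}})
        df = cohort_frame(generate_cohort(
            40, effects=eff, seed=9, melatonin_fraction=0.0,
            include_white=False))
        row = fully_adjusted_model(df, "hdl", "ble_acrophase_h")
        assert row.estimate < 0
        assert row.p < 0.01


class TestVIF:
    def test_orthogonal_columns(self):
        n = 64
        X = np.column_stack([np.cos(2 * np.pi * np.arange(n) / n),
                             np.sin(2 * np.pi * np.arange(n) / n)])
        assert vif(X) == pytest.approx([1.0, 1.0], abs=1e-10)

    def test_correlated_pair_closed_form(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=500)
        b = rng.normal(size=500)
        # Gram-Schmidt for an exact sample correlation of 0.9
        a = (a - a.mean()) / a.std(ddof=1)
        b = b - b.mean()
        b -= a * np.sum(a * b) / np.sum(a * a)
        b /= b.std(ddof=1)
        x2 = 0.9 * a + np.sqrt(1 - 0.81) * b
        out = vif(np.column_stack([a, x2]))
        assert out == pytest.approx([1 / (1 - 0.81)] * 2, abs=1e-9)

    def test_three_columns_match_statsmodels(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 3))
        X[:, 2] += 0.8 * X[:, 0]
        ours = vif(X)
        Xc = np.column_stack([X, np.ones(200)])
        ref = [variance_inflation_factor(Xc, j) for j in range(3)]
        assert ours == pytest.approx(ref, rel=1e-8)

    def test_perfect_collinearity_flagged_infinite(self):
        x = np.random.default_rng(1).normal(size=50)
        assert np.isinf(vif(np.column_stack([x, 2 * x]))).all()


class TestCompareSeasons:
    @staticmethod
    def frame(ws, se, ss):
        return pd.DataFrame({
            "season": ["WS"] * len(ws) + ["SE"] * len(se) + ["SS"] * len(ss),
            "v": np.concatenate([ws, se, ss]),
        })

    def test_normal_data_routes_parametric(self):
        rng = np.random.default_rng(2)
        res = compare_seasons(self.frame(rng.normal(0, 1, 27),
                                         rng.normal(0, 1, 27),
                                         rng.normal(0, 1, 27)), "v")
        assert res.routing == "parametric" and res.test == "anova"

    def test_lognormal_data_routes_rank_tests(self):
        rng = np.random.default_rng(3)
        res = compare_seasons(self.frame(rng.lognormal(0, 1.2, 27),
                                         rng.lognormal(0, 1.2, 27),
                                         rng.lognormal(0, 1.2, 27)), "v")
        assert res.routing == "nonparametric" and res.test == "kruskal"

    def test_large_shift_detected(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({
            "season": ["WS"] * 27 + ["SE"] * 27,
            "v": np.concatenate([rng.normal(0, 1, 27),
                                 rng.normal(5, 1, 27)]),
        })
        assert compare_seasons(df, "v").p < 0.001

    def test_kruskal_null_rejection_rate(self):
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(500):
            df = self.frame(rng.exponential(1, 15), rng.exponential(1, 15),
                            rng.exponential(1, 15))
            hits += compare_seasons(df, "v", routing="nonparametric").p < 0.05
        assert 0.03 <= hits / 500 <= 0.07

    def test_single_season_raises(self):
        df = pd.DataFrame({"season": ["WS"] * 9, "v": np.arange(9.0)})
        with pytest.raises(InsufficientDataError):
            compare_seasons(df, "v")


class TestCircularLinearization:
    def test_wraparound_values_become_adjacent(self):
        out = linearize_circular(np.array([23.5, 0.5, 23.8, 0.2]))
        assert np.ptp(out) < 1.5

    def test_participant_season_validation(self):
        with pytest.raises(ValidationError):
            ParticipantSeason("s", 30, "male", "NN", "XX",
                              tc=5, ldl=3, hdl=1.4, tg=1.2)
        with pytest.raises(ValidationError):
            ParticipantSeason("s", 30, "male", "NN", "WS",
                              tc=5, ldl=3, hdl=-1.0, tg=1.2)
        p = ParticipantSeason("s", 30, "male", "NN", "WS",
                              tc=5, ldl=3, hdl=1.25, tg=2.5)
        assert p.tg_hdl == pytest.approx(2.0)
        assert p.photoperiod_h == 1
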
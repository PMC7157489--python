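import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from artstat.errors import (
    DegeneratePredictorError,
    InsufficientDataError,
    InvalidInputError,
    UndefinedStatisticError,
)
from artstat.plsr import (
    correlation_table,
    fdr_adjust,
    first_k_reaching,
    fit_plsr,
    pearson_cd,
    rescale_ratings,
    run_genre_analysis,
    select_ncomp,
    vip_scores,
    zscore_predictors,
)
from artstat.stats import STAT_COLUMNS
from artstat.synthetic import gen_genre_dataset, gen_rating_dataset, noise_sd_for_r2

from conftest import records_from_arrays


class TestRescaleRatings:
    def test_endpoints_and_midpoint(self):
        np.testing.assert_allclose(
            rescale_ratings([1.0, 4.0, 7.0]), [0.0, 50.0, 100.0]
        )

    def test_interior_value(self):
        assert rescale_ratings([2.5])[0] == pytest.approx(25.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            rescale_ratings([0.5])
        with pytest.raises(InvalidInputError):
            rescale_ratings([7.2])


class TestPearsonCd:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, cd, p = pearson_cd(x, 2 * x + 1)
        assert r == pytest.approx(1.0) and cd == pytest.approx(100.0)

    def test_constructed_orthogonality(self):
        x = np.array([-1.0, 0.0, 1.0, 0.0])
        y = np.array([0.0, 1.0, 0.0, -1.0])
        r, cd, _ = pearson_cd(x, y)
        assert r == pytest.approx(0.0, abs=1e-12)
        assert cd == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_five_pairs(self):
        # sum of cross-products 8, each sum of squares 10 -> r = 0.8
        r, cd, p = pearson_cd([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert r == pytest.approx(0.8)
        assert cd == pytest.approx(64.0)
        assert 0.0 < p < 1.0

    def test_missing_pairs_dropped(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 4.0, 100.0, 8.0, 10.0]
        r, _, _ = pearson_cd(x, y)
        assert r == pytest.approx(1.0)

    def test_degenerate_inputs(self):
        with pytest.raises(InsufficientDataError):
            pearson_cd([1.0, 2.0], [3.0, 4.0])
        with pytest.raises(UndefinedStatisticError):
            pearson_cd([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_cd_invariant_to_rating_rescale(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        scores7 = rng.uniform(1, 7, 30)
        _, cd_raw, _ = pearson_cd(x, scores7)
        _, cd_scaled, _ = pearson_cd(x, rescale_ratings(scores7))
        assert cd_scaled == pytest.approx(cd_raw, abs=1e-10)


class TestFdr:
    def test_all_tiny_all_flagged(self):
        assert fdr_adjust([0.001] * 9).all()

    def test_all_large_none_flagged(self):
        assert not fdr_adjust([0.9] * 9).any()

    def test_step_up_rule_by_hand(self):
        # largest k with p(k) <= 0.05*k/5 is k=4 -> first four rejected
        flags = fdr_adjust([0.001, 0.01, 0.02, 0.04, 0.2])
        assert flags.tolist() == [True, True, True, True, False]

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(InvalidInputError):
            fdr_adjust([0.5, 1.2])


class TestZscore:
    def test_simple_column(self):
        Z, mean, sd = zscore_predictors(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(Z.ravel(), [-1.0, 0.0, 1.0])
        assert mean[0] == 2.0 and sd[0] == 1.0

    def test_idempotent_on_standardized(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 3))
        Z, _, _ = zscore_predictors(X)
        Z2, _, _ = zscore_predictors(Z)
        np.testing.assert_allclose(Z2, Z, atol=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(DegeneratePredictorError):
            zscore_predictors(np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]))


class TestFitPlsr:
    def test_noiseless_full_rank_reaches_100(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 9))
        Z, _, _ = zscore_predictors(X)
        y = Z @ np.arange(1.0, 10.0)
        assert fit_plsr(Z, y, 9).cd_fit == pytest.approx(100.0, abs=1e-6)

    def test_independent_noise_explains_little(self):
        cds = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            Z, _, _ = zscore_predictors(rng.normal(size=(2000, 9)))
            cds.append(fit_plsr(Z, rng.normal(size=2000), 1).cd_fit)
        assert np.mean(cds) < 2.0

    def test_nested_fits_nondecreasing(self, rating_dataset):
        df, _ = rating_dataset
        Z, _, _ = zscore_predictors(df[list(STAT_COLUMNS)].to_numpy())
        y = df["rating"].to_numpy()
        curve = [fit_plsr(Z, y, k).cd_fit for k in range(1, 10)]
        assert all(b >= a - 1e-9 for a, b in zip(curve, curve[1:]))

    def test_matches_ols_at_full_rank(self, rating_dataset):
        df, _ = rating_dataset
        Z, _, _ = zscore_predictors(df[list(STAT_COLUMNS)].to_numpy())
        y = df["rating"].to_numpy()
        A = np.column_stack([np.ones(len(y)), Z])
        resid = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
        r2 = 100.0 * (1.0 - resid @ resid / np.sum((y - y.mean()) ** 2))
        assert fit_plsr(Z, y, 9).cd_fit == pytest.approx(r2, abs=1e-6)

    def test_k_out_of_range_rejected(self):
        rng = np.random.default_rng(3)
        Z, _, _ = zscore_predictors(rng.normal(size=(20, 9)))
        y = rng.normal(size=20)
        for bad in (0, 10):
            with pytest.raises(InvalidInputError):
                fit_plsr(Z, y, bad)

    def test_scale_invariance_of_cd_and_vip(self, rating_dataset):
        df, _ = rating_dataset
        X = df[list(STAT_COLUMNS)].to_numpy().copy()
        y = df["rating"].to_numpy()
        Z1, _, _ = zscore_predictors(X)
        m1 = fit_plsr(Z1, y, 3)
        X[:, 4] = -7.0 * X[:, 4] + 100.0  # affine rescale of one column
        Z2, _, _ = zscore_predictors(X)
        m2 = fit_plsr(Z2, y, 3)
        assert m2.cd_fit == pytest.approx(m1.cd_fit, abs=1e-8)
        np.testing.assert_allclose(m2.vip, m1.vip, atol=1e-8)


class TestSelectNcomp:
    def test_elbow_curve(self):
        curve = [40, 76, 78, 79, 80, 80, 80, 80, 80]
        assert first_k_reaching(curve, 0.85) == 2

    def test_flat_curve_picks_one(self):
        assert first_k_reaching([50.0] * 9, 0.85) == 1

    def test_linear_ramp(self):
        # ramp to 90: threshold 76.5 first crossed at k = 8
        curve = np.linspace(90.0 / 9.0, 90.0, 9)
        assert first_k_reaching(curve, 0.85) == 8

    def test_on_fitted_curve(self, rating_dataset):
        df, _ = rating_dataset
        Z, _, _ = zscore_predictors(df[list(STAT_COLUMNS)].to_numpy())
        y = df["rating"].to_numpy()
        k = select_ncomp(Z, y)
        curve = [fit_plsr(Z, y, j).cd_fit for j in range(1, 10)]
        assert curve[k - 1] >= 0.85 * curve[-1]
        assert k == 1 or curve[k - 2] < 0.85 * curve[-1]


class TestVip:
    def test_equal_weights_all_unity(self):
        # orthonormal-ish predictors, y loading equally on all nine
        rng = np.random.default_rng(4)
        X = rng.normal(size=(90, 9))
        Q, _ = np.linalg.qr(X - X.mean(axis=0))  # centred, exactly orthogonal
        Z, _, _ = zscore_predictors(Q)
        y = Z.sum(axis=1)
        m = fit_plsr(Z, y, 1)
        np.testing.assert_allclose(m.vip, 1.0, atol=1e-8)
        assert m.selected == ()

    def test_single_active_orthogonal_predictor(self):
        # X columns exactly orthogonal, y = column 0: all weight on one
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 9))
        Q, _ = np.linalg.qr(X - X.mean(axis=0))
        Z, _, _ = zscore_predictors(Q)
        y = Z[:, 0].copy()
        m = fit_plsr(Z, y, 1)
        assert m.vip[0] == pytest.approx(3.0, abs=1e-8)
        np.testing.assert_allclose(m.vip[1:], 0.0, atol=1e-8)
        assert m.selected == (STAT_COLUMNS[0],)

    @given(seed=st.integers(0, 10_000))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_mean_squared_vip_is_one(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        k = int(rng.integers(1, 10))
        Z, _, _ = zscore_predictors(rng.normal(size=(n, 9)))
        y = Z @ rng.normal(size=9) + rng.normal(size=n)
        m = fit_plsr(Z, y, min(k, n - 1))
        assert np.mean(m.vip**2) == pytest.approx(1.0, abs=1e-10)

    def test_unfitted_model_rejected(self):
        from artstat.plsr import PLSRModel

        empty = PLSRModel(predictors=STAT_COLUMNS, n_comp=0,
                          x_weights=np.empty((9, 0)),
                          x_loadings=np.empty((9, 0)),
                          y_loadings=np.empty(0),
                          x_scores=np.empty((0, 0)), cd_fit=0.0)
        with pytest.raises(InvalidInputError):
            vip_scores(empty)


class TestGenreAnalysis:
    def test_active_statistic_dominates(self):
        w = np.zeros(9)
        w[6] = 1.0  # EN_L drives ratings
        df, _ = gen_rating_dataset(150, w, noise_sd_for_r2(w, 0.8), seed=21,
                                   genre="landscape")
        corr, model = run_genre_analysis(df, "landscape")
        best_cd = corr.loc[corr["Cd"].idxmax(), "statistic"]
        assert best_cd == "EN_L"
        assert model.predictors[int(np.argmax(model.vip))] == "EN_L"

    def test_distinct_actives_recovered_per_genre(self):
        specs = {
            "nude": {"n": 120, "weights": np.eye(9)[0],
                     "noise_sd": 0.5},          # SL_L active
            "landscape": {"n": 120, "weights": np.eye(9)[6],
                          "noise_sd": 0.5},     # EN_L active
        }
        df, _ = gen_genre_dataset(specs, seed=8)
        _, m_nude = run_genre_analysis(df, "nude")
        _, m_land = run_genre_analysis(df, "landscape")
        assert m_nude.predictors[int(np.argmax(m_nude.vip))] == "SL_L"
        assert m_land.predictors[int(np.argmax(m_land.vip))] == "EN_L"

    def test_small_genre_rejected(self, rating_dataset):
        df, _ = rating_dataset
        small = df.iloc[:5].assign(genre="nude")
        with pytest.raises(InsufficientDataError):
            run_genre_analysis(small, "nude")

    def test_correlation_table_layout(self, null_genre_dataset):
        df, _ = null_genre_dataset
        table = correlation_table(df)
        assert set(table["genre"]) == set(df["genre"]) | {"all"}
        assert len(table) == 9 * (df["genre"].nunique() + 1)
        finite = table[np.isfinite(table["Cd"])]
        np.testing.assert_allclose(
            finite["Cd"], 100.0 * finite["r"] ** 2, atol=1e-12
        )

    def test_flagged_statistics_dropped_pairwise(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(40, 9))
        y = X[:, 0] + rng.normal(size=40)
        X[:5, 0] = np.nan  # flagged SL values for a few images
        df = records_from_arrays(X, y)
        table = correlation_table(df)
        row = table[(table["genre"] == "all") & (table["statistic"] == "SL_L")]
        assert int(row["n"].iloc[0]) == 35
        assert np.isfinite(row["r"].iloc[0])
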
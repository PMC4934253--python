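import numpy as np
import pytest

from localpls import fit_pls, press_trace, rmsecv_loo, rmsep, select_factors


def brute_force_press(X, Y, kmax):
    """Fold-by-fold LOO refits using the public fit_pls API plus an
    independently computed per-fold prediction."""
    m = X.shape[0]
    press = np.zeros(kmax)
    for k in range(1, kmax + 1):
        total = 0.0
        for j in range(m):
            mask = np.ones(m, bool)
            mask[j] = False
            model = fit_pls(X[mask], Y[mask], k)
            pred = model.predict(X[j][None, :])[0]
            total += float(((Y[j] - pred) ** 2).sum())
        press[k - 1] = total
    return press


class TestFit:
    def test_exact_interpolation_of_linear_map(self, rng):
        X = rng.normal(size=(12, 6))
        B = rng.normal(size=(6, 3))
        Y = X @ B
        model = fit_pls(X, Y, 6)
        np.testing.assert_allclose(model.predict(X), Y, atol=1e-8)

    def test_rank_two_data_exact_with_two_factors(self, rng):
        # spectra of rank 2: two factors exhaust X, so training residuals vanish
        T = rng.normal(size=(10, 2))
        X = T @ rng.normal(size=(2, 5))
        Y = X @ rng.normal(size=(5, 2))
        model = fit_pls(X, Y, 2)
        np.testing.assert_allclose(model.predict(X), Y, atol=1e-8)

    def test_mean_spectrum_predicts_mean_response(self, rng):
        X = rng.normal(size=(9, 7))
        Y = rng.normal(size=(9, 2))
        model = fit_pls(X, Y, 3)
        np.testing.assert_allclose(
            model.predict(X.mean(axis=0)[None, :])[0], Y.mean(axis=0), atol=1e-10
        )

    def test_single_factor_matches_closed_form(self, rng):
        # one-factor PLS1 equals least squares of y on the first score t = Xc w,
        # with w proportional to Xc^T y
        X = rng.normal(size=(15, 6))
        y = rng.normal(size=15)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        w = Xc.T @ yc
        w /= np.linalg.norm(w)
        t = Xc @ w
        slope = float(t @ yc / (t @ t))
        expect = y.mean() + slope * ((X - X.mean(axis=0)) @ w)
        model = fit_pls(X, y, 1)
        np.testing.assert_allclose(model.predict(X)[:, 0], expect, atol=1e-10)

    def test_offset_in_y_absorbed_by_centering(self, rng):
        X = rng.normal(size=(10, 5))
        Y = rng.normal(size=(10, 2))
        m1 = fit_pls(X, Y, 3)
        m2 = fit_pls(X, Y + 100.0, 3)
        np.testing.assert_allclose(m1.predict(X) + 100.0, m2.predict(X), atol=1e-8)

    def test_rank_deficiency_warns_and_truncates(self, rng):
        x = rng.normal(size=10)
        X = np.column_stack([x, 2 * x, -x])  # rank-1 predictors
        Y = (x * 3.0)[:, None]
        with pytest.warns(RuntimeWarning):
            model = fit_pls(X, Y, 2)
        assert model.n_factors == 1

    def test_matches_sklearn_on_well_conditioned_data(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(30, 10))
        Y = X @ rng.normal(size=(10, 2)) + 0.1 * rng.normal(size=(30, 2))
        for k in (1, 2, 4):
            ours = fit_pls(X, Y, k).predict(X)
            ref = sklearn.PLSRegression(n_components=k, scale=False).fit(X, Y).predict(X)
            # sklearn's NIPALS stops its inner iteration at 1e-6, so agreement
            # is only expected to slightly better than that level
            np.testing.assert_allclose(ours, ref, rtol=2e-3, atol=2e-3)

    def test_coef_consistent_with_iterative_prediction(self, rng):
        X = rng.normal(size=(12, 8))
        Y = rng.normal(size=(12, 3))
        model = fit_pls(X, Y, 4)
        via_coef = (X - model.x_mean) @ model.coef + model.y_mean
        np.testing.assert_allclose(model.predict(X), via_coef, atol=1e-9)

    def test_serialization_round_readable(self, rng):
        model = fit_pls(rng.normal(size=(6, 4)), rng.normal(size=(6, 1)), 2)
        text = model.to_text()
        assert text.startswith("n_factors: 2")
        assert "weights:" in text


class TestPress:
    def test_noiseless_rank_one_press_negligible(self, rng):
        x = rng.normal(size=9)
        X = np.outer(x, rng.normal(size=5))
        Y = (2.0 * x)[:, None]
        press = press_trace(X, Y, 1)
        assert press[0] <= 1e-16 * float((Y**2).sum())

    def test_matches_brute_force_loo_oracle(self, rng):
        X = rng.normal(size=(5, 4))
        Y = rng.normal(size=(5, 2))
        got = press_trace(X, Y, 3)
        want = brute_force_press(X, Y, 3)
        np.testing.assert_allclose(got, want, atol=1e-10)
        assert np.all(got >= 0)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            press_trace(rng.normal(size=(2, 3)), rng.normal(size=(2, 1)), 1)


class TestFactorRule:
    @pytest.mark.parametrize(
        "trace,expected",
        [
            ((10.0, 5.0, 6.0), 2),
            ((10.0, 11.0, 3.0), 1),
            ((10.0, 8.0, 5.0, 3.0, 1.0), 5),
            ((7.0,), 1),
            ((4.0, 0.0, 0.0), 2),  # exact zero stops growth
        ],
    )
    def test_first_upturn_rule(self, trace, expected):
        assert select_factors(np.array(trace)) == expected

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            select_factors(np.array([]))


class TestMetrics:
    def test_perfect_prediction_zero(self, rng):
        Y = rng.normal(size=(6, 3))
        np.testing.assert_array_equal(rmsep(Y, Y), np.zeros(3))

    def test_hand_residuals(self):
        y = np.array([[0.0], [0.0]])
        yhat = np.array([[3.0], [4.0]])
        assert rmsep(y, yhat)[0] == pytest.approx(np.sqrt(12.5))

    def test_matches_elementwise_formula(self, rng):
        y = rng.normal(size=(8, 3))
        yhat = rng.normal(size=(8, 3))
        want = [np.sqrt(np.mean((y[:, a] - yhat[:, a]) ** 2)) for a in range(3)]
        np.testing.assert_allclose(rmsep(y, yhat), want, atol=1e-14)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmsep(np.zeros((3, 2)), np.zeros((3, 3)))


class TestRMSECV:
    def test_constant_responses_give_zero(self, rng):
        X = rng.normal(size=(8, 5))
        Y = np.full((8, 2), 42.0)
        assert rmsecv_loo(X, Y) == 0.0

    @pytest.mark.parametrize("rule", ["pooled_press", "per_fold"])
    def test_matches_brute_force_oracle(self, rng, rule):
        X = rng.normal(size=(6, 4))
        Y = rng.normal(size=(6, 2))
        got = rmsecv_loo(X, Y, kmax=2, factor_rule=rule)
        # independent fold-by-fold recomputation
        m = X.shape[0]
        press = brute_force_press(X, Y, 2)
        sq = []
        for j in range(m):
            mask = np.ones(m, bool)
            mask[j] = False
            if rule == "pooled_press":
                k = select_factors(press)
            else:
                k = select_factors(brute_force_press(X[mask], Y[mask], 2))
            pred = fit_pls(X[mask], Y[mask], k).predict(X[j][None, :])[0]
            sq.extend(((Y[j] - pred) ** 2).tolist())
        assert got == pytest.approx(float(np.sqrt(np.mean(sq))), abs=1e-10)

    def test_too_small_rejected(self, rng):
        with pytest.raises(ValueError):
            rmsecv_loo(rng.normal(size=(2, 3)), rng.normal(size=(2, 1)))
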
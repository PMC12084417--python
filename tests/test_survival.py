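"""SVD compression, logistic fits, extrapolation and gamma curve fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prognosim import survival
from prognosim.survival import SvdBasis, SubsetModel


def standardized(rng, n, p):
    X = rng.standard_normal((n, p))
    return (X - X.mean(0)) / X.std(0)


def make_model(beta0, beta, basis, t=2):
    return SubsetModel(
        t=t, beta0=beta0, beta=np.asarray(beta, dtype=float), basis=basis,
        cv_auc=0.5, folds=2,
    )


def random_basis(rng, n, m):
    q, _ = np.linalg.qr(rng.standard_normal((n, n)))
    return SvdBasis(q[:, :m].copy(), np.ones(n), 1.0, m)


class TestFitSvd:
    def test_rank_one_needs_single_vector(self, rng):
        u = rng.standard_normal((50, 1))
        v = rng.standard_normal((1, 6))
        basis = survival.fit_svd(u @ v, var_target=0.9)
        assert basis.m == 1

    def test_full_variance_target_keeps_rank(self, rng):
        X = standardized(rng, 40, 5)
        assert survival.fit_svd(X, var_target=1.0).m == np.linalg.matrix_rank(X)

    def test_m_nondecreasing_in_var_target(self, rng):
        X = standardized(rng, 100, 10)
        ms = [survival.fit_svd(X, v).m for v in (0.3, 0.5, 0.7, 0.9, 0.99)]
        assert all(a <= b for a, b in zip(ms, ms[1:]))

    def test_columns_orthonormal(self, rng):
        basis = survival.fit_svd(standardized(rng, 80, 6), 0.9)
        gram = basis.omega.T @ basis.omega
        np.testing.assert_allclose(gram, np.eye(basis.m), atol=1e-10)

    def test_m_nondecreasing_with_dataset_growth(self, rng):
        """Nested subsets of growing size retain at least as many vectors."""
        X = standardized(rng, 400, 12) @ np.diag(np.linspace(2.0, 0.2, 12))
        ms = [survival.fit_svd(X[:n], 0.9).m for n in (50, 100, 200, 400)]
        assert all(a <= b for a, b in zip(ms, ms[1:]))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            survival.fit_svd(np.empty((0, 3)))


class TestProject:
    def test_identity_basis_is_identity(self, rng):
        X = rng.standard_normal((10, 4))
        basis = SvdBasis(np.eye(4), np.ones(4), 1.0, 4)
        np.testing.assert_array_equal(survival.project(X, basis), X)

    def test_zero_row_maps_to_zero(self, rng):
        X = rng.standard_normal((5, 4))
        X[2] = 0.0
        basis = survival.fit_svd(standardized(rng, 30, 4), 0.9)
        assert np.all(survival.project(X, basis)[2] == 0.0)

    def test_truncation_residual_bound(self, rng):
        X = standardized(rng, 60, 8)
        var_target = 0.8
        basis = survival.fit_svd(X, var_target)
        recon = survival.project(X, basis) @ basis.omega.T
        resid = np.linalg.norm(X - recon) ** 2
        assert resid <= (1.0 - var_target) * np.linalg.norm(X) ** 2 + 1e-9

    def test_shape_mismatch_rejected(self, rng):
        basis = survival.fit_svd(standardized(rng, 30, 4), 0.9)
        with pytest.raises(ValueError):
            survival.project(np.zeros((3, 7)), basis)


class TestFitLogistic:
    def test_null_features_give_chance_auc(self, rng):
        SV = rng.standard_normal((2000, 3))
        y = rng.integers(0, 2, 2000)
        model = survival.fit_logistic(SV, y, folds=20, seed=0)
        assert model.cv_auc == pytest.approx(0.5, abs=0.05)

    def test_strong_signal_gives_high_auc(self, rng):
        SV = rng.standard_normal((800, 3))
        y = (SV[:, 0] * 3 + 0.3 * rng.standard_normal(800) > 0).astype(int)
        model = survival.fit_logistic(SV, y, folds=10, seed=0)
        assert model.cv_auc > 0.9

    def test_deterministic_given_seed(self, rng):
        SV = rng.standard_normal((300, 4))
        y = rng.integers(0, 2, 300)
        a = survival.fit_logistic(SV, y, folds=5, seed=3)
        b = survival.fit_logistic(SV, y, folds=5, seed=3)
        assert a.beta0 == b.beta0
        np.testing.assert_array_equal(a.beta, b.beta)
        assert a.cv_auc == b.cv_auc

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            survival.fit_logistic(rng.standard_normal((20, 2)), np.zeros(20))

    def test_permuted_labels_chance_level(self, rng):
        """Label permutation destroys the AUC of a genuinely informative fit."""
        SV = rng.standard_normal((1500, 3))
        y = (SV[:, 0] + rng.standard_normal(1500) > 0).astype(int)
        real = survival.fit_logistic(SV, y, folds=10, seed=0).cv_auc
        perm = survival.fit_logistic(SV, rng.permutation(y), folds=10, seed=0).cv_auc
        assert real > 0.7
        assert perm == pytest.approx(0.5, abs=0.06)


class TestPredictProb:
    def test_zero_coefficients_give_half(self, rng):
        basis = random_basis(rng, 5, 3)
        model = make_model(0.0, [0.0, 0.0, 0.0], basis)
        np.testing.assert_allclose(
            survival.predict_prob(model, rng.standard_normal((7, 5))), 0.5
        )

    def test_output_strictly_inside_unit_interval(self, rng):
        basis = random_basis(rng, 4, 2)
        model = make_model(1.5, [2.0, -3.0], basis)
        p = survival.predict_prob(model, 10 * rng.standard_normal((50, 4)))
        assert np.all((p > 0) & (p < 1))

    def test_sv_and_feature_space_agree_to_machine_precision(self, rng):
        """Projection-then-logistic equals composed-coefficient logistic."""
        for _ in range(100):
            n, m = rng.integers(3, 10), rng.integers(1, 3)
            basis = random_basis(rng, int(n), int(m))
            model = make_model(rng.normal(), rng.normal(size=int(m)), basis)
            X = rng.standard_normal((20, int(n)))
            p_sv = survival.predict_prob(model, X, space="sv")
            p_ft = survival.predict_prob(model, X, space="feature")
            np.testing.assert_allclose(p_sv, p_ft, atol=1e-12, rtol=0)


class TestTheta:
    def _linear_models(self, rng, slope0=0.2, t_values=(2, 3, 4, 5)):
        basis = random_basis(rng, 4, 2)
        slopes = np.array([0.5, -0.3])
        models = [
            make_model(1.0 + slope0 * t, [0.1 + slopes[0] * t, slopes[1] * t], basis, t=t)
            for t in t_values
        ]
        return models, basis, slopes, slope0

    def test_constant_betas_give_zero_theta(self, rng):
        basis = random_basis(rng, 4, 2)
        models = [make_model(0.4, [1.0, -0.5], basis, t=t) for t in (2, 3, 4)]
        ev = survival.theta(models, rng.standard_normal((6, 4)), t=3)
        np.testing.assert_allclose(ev.theta, 0.0, atol=1e-12)

    def test_linear_betas_recover_exact_slope(self, rng):
        models, basis, slopes, slope0 = self._linear_models(rng)
        X = rng.standard_normal((8, 4))
        ev = survival.theta(models, X, t=3, mode="paper")
        expected = slope0 + X @ (basis.omega @ slopes)
        np.testing.assert_allclose(ev.theta, expected, atol=1e-10)

    def test_taylor_mode_applies_chain_rule(self, rng):
        models, _, _, _ = self._linear_models(rng)
        X = rng.standard_normal((5, 4))
        ev = survival.theta(models, X, t=2, mode="taylor")
        model = models[0]
        f = survival.predict_prob(model, X)
        np.testing.assert_allclose(ev.dfdt, f * (1 - f) * ev.theta, atol=1e-12)

    def test_single_model_rejected(self, rng):
        basis = random_basis(rng, 3, 2)
        with pytest.raises(ValueError):
            survival.theta([make_model(0.0, [1.0, 1.0], basis)], np.zeros((1, 3)))

    def test_mismatched_bases_rejected(self, rng):
        m1 = make_model(0.0, [1.0], random_basis(rng, 3, 1), t=2)
        m2 = make_model(0.0, [1.0], random_basis(rng, 3, 1), t=3)
        with pytest.raises(ValueError):
            survival.theta([m1, m2], np.zeros((1, 3)))


class TestExtrapolate:
    def test_zero_theta_or_dt_is_identity(self):
        assert survival.extrapolate(0.7, 0.0, 0.5) == pytest.approx(0.7)
        assert survival.extrapolate(0.7, 2.0, 0.0) == pytest.approx(0.7)

    @settings(deadline=None, derandomize=True)
    @given(
        f=st.floats(0.01, 0.99),
        th=st.floats(-3, 3),
        dt=st.floats(0, 0.5),
    )
    def test_variant_slope_algebraic_identity(self, f, th, dt):
        # f·(θΔt + 1) − θΔt == f + (f − 1)·θ·Δt
        direct = np.clip(f * (th * dt + 1.0) - th * dt, 0.0, 1.0)
        assert survival.extrapolate(f, th, dt, mode="paper") == pytest.approx(
            direct, abs=1e-12
        )

    def test_second_order_error_for_linear_beta_drift(self, rng):
        """Taylor step error shrinks ~Δt² when the logit drifts linearly."""
        z0, zdot = 0.4, 1.3
        f = lambda t: 1.0 / (1.0 + np.exp(-(z0 + zdot * t)))
        theta_val = zdot
        dts = np.array([0.2, 0.1, 0.05, 0.025])
        errs = [
            abs(f(dt) - survival.extrapolate(f(0.0), theta_val, dt, mode="taylor"))
            for dt in dts
        ]
        slope = np.polyfit(np.log(dts), np.log(errs), 1)[0]
        assert slope == pytest.approx(2.0, abs=0.1)

    def test_clamped_to_unit_interval(self):
        assert survival.extrapolate(0.9, 10.0, 1.0, mode="taylor") <= 1.0
        assert survival.extrapolate(0.1, -10.0, 1.0, mode="taylor") >= 0.0

    def test_probability_outside_open_interval_rejected(self):
        with pytest.raises(ValueError):
            survival.extrapolate(1.0, 0.1, 0.1)


class TestLogisticDerivative:
    def test_quarter_at_origin(self):
        numeric, closed = survival.logistic_derivative_check(0.0)
        assert closed == pytest.approx(0.25)
        assert numeric == pytest.approx(0.25, abs=1e-8)

    def test_even_symmetry(self, rng):
        for x in rng.uniform(-4, 4, 20):
            _, plus = survival.logistic_derivative_check(x)
            _, minus = survival.logistic_derivative_check(-x)
            assert plus == pytest.approx(minus, rel=1e-12)

    def test_numeric_matches_closed_form_and_sech(self, rng):
        for x in rng.uniform(-5, 5, 50):
            numeric, closed = survival.logistic_derivative_check(x)
            assert abs(numeric - closed) < 1e-8
            sech_form = 0.25 / np.cosh(x / 2.0) ** 2
            assert closed == pytest.approx(sech_form, rel=1e-12)


class TestGammaFit:
    def test_parameter_recovery_on_model_data(self):
        x = np.linspace(0.0, 20.0, 80)
        true = survival.GammaFit(2.0, 3.0, 0.8, 0.1, 0.0)
        fit = survival.fit_gamma_cdf(x, true.predict(x))
        assert fit.shape == pytest.approx(2.0, rel=0.01)
        assert fit.scale == pytest.approx(3.0, rel=0.01)
        assert fit.amplitude == pytest.approx(0.8, rel=0.01)
        assert fit.offset == pytest.approx(0.1, rel=0.01)

    def test_returned_optimum_beats_perturbations(self, rng):
        x = np.linspace(0.0, 15.0, 40)
        p = 0.6 * np.exp(-x / 4.0) + 0.2 + 0.02 * rng.standard_normal(40)
        fit = survival.fit_gamma_cdf(x, p)

        def sse(k, th, a, c):
            from scipy import stats

            return float(np.sum((a * stats.gamma.sf(x, k, scale=th) + c - p) ** 2))

        base = sse(fit.shape, fit.scale, fit.amplitude, fit.offset)
        for _ in range(10):
            jitter = 1.0 + 0.1 * rng.standard_normal(4)
            assert base <= sse(
                fit.shape * jitter[0], fit.scale * jitter[1],
                fit.amplitude * jitter[2], fit.offset * jitter[3],
            ) + 1e-12

    def test_constant_probabilities_fit_flat_curve(self):
        x = np.linspace(0.0, 10.0, 20)
        fit = survival.fit_gamma_cdf(x, np.full(20, 0.4))
        assert fit.sse == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(fit.predict(x), 0.4, atol=1e-5)

    def test_fitted_curve_monotone_when_amplitude_positive(self):
        x = np.linspace(0.0, 20.0, 50)
        fit = survival.GammaFit(1.5, 2.0, 0.7, 0.15, 0.0)
        vals = fit.predict(x)
        assert np.all(np.diff(vals) <= 1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            survival.fit_gamma_cdf([1.0, 2.0, 3.0], [0.5, 0.4, 0.3])


def test_model_json_round_trip(rng):
    basis = random_basis(rng, 5, 2)
    basis = SvdBasis(basis.omega, basis.singular_values, 0.9, 2, ("a", "b", "c", "d", "e"))
    models = [make_model(0.1 * t, [0.2 * t, -0.1 * t], basis, t=t) for t in (2, 3, 4)]
    back = survival.models_from_json(survival.models_to_json(models))
    assert [m.t for m in back] == [2, 3, 4]
    np.testing.assert_allclose(back[0].basis.omega, basis.omega)
    np.testing.assert_allclose(back[1].beta, models[1].beta)
    X = rng.standard_normal((4, 5))
    np.testing.assert_allclose(
        survival.predict_prob(back[2], X), survival.predict_prob(models[2], X)
    )
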
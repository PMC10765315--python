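"""Causal estimators: Wald, correlated IVW, Egger, PCA-IVW, Steiger."""

import numpy as np
import pytest
from scipy import stats

from targetmr import (
    egger_correlated,
    estimate_auto,
    ivw_correlated,
    pca_ivw,
    steiger_filter,
    variance_explained,
    wald_ratio,
)

from conftest import ar1, make_hset, random_psd_corr


def _random_instance(rng, m, theta=0.3):
    rho = random_psd_corr(rng, m)
    b_x = rng.normal(0, 0.1, m)
    se_y = rng.uniform(0.005, 0.05, m)
    chol = np.linalg.cholesky(np.outer(se_y, se_y) * rho + 1e-12 * np.eye(m))
    b_y = theta * b_x + chol @ rng.standard_normal(m)
    return make_hset(b_x, b_y, se_Y=se_y, rho=rho)


def gls_oracle(X, y, omega):
    """Independent GLS via explicit matrix inversion (no whitening)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    oi = np.linalg.inv(np.asarray(omega, dtype=float))
    cov = np.linalg.inv(X.T @ oi @ X)
    beta = cov @ (X.T @ oi @ np.asarray(y, dtype=float))
    return beta, cov


class TestWaldRatio:
    def test_arithmetic(self):
        h = make_hset([0.5], [0.1], se_Y=[0.02])
        est = wald_ratio(h)
        assert est.theta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.04)
        assert est.method == "wald"

    def test_null_outcome(self):
        est = wald_ratio(make_hset([0.5], [0.0], se_Y=[0.02]))
        assert est.theta == 0.0 and est.p == 1.0

    def test_zero_exposure_effect_errors(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(make_hset([0.0], [0.1]))

    def test_first_order_se_matches_monte_carlo(self, rng):
        reps = 100_000
        bx = 0.5 + 0.01 * rng.standard_normal(reps)
        by = 0.1 + 0.02 * rng.standard_normal(reps)
        empirical = np.std(by / bx)
        assert abs(empirical - 0.02 / 0.5) / (0.02 / 0.5) < 0.05


class TestIVWCorrelated:
    def test_equal_weight_mean_two_variants(self):
        h = make_hset([1.0, 1.0], [0.2, 0.4], se_Y=[0.1, 0.1])
        est = ivw_correlated(h)
        assert est.method == "ivw_fixed"
        assert est.theta == pytest.approx(0.3)
        assert est.se == pytest.approx(0.1 / np.sqrt(2))

    def test_identity_rho_reduces_to_classic_ivw(self, rng):
        m = 3
        b_x = rng.normal(0, 0.1, m)
        b_y = rng.normal(0, 0.01, m)
        se_y = rng.uniform(0.005, 0.05, m)
        est = ivw_correlated(make_hset(b_x, b_y, se_Y=se_y))
        classic = np.sum(b_x * b_y / se_y**2) / np.sum(b_x**2 / se_y**2)
        assert est.theta == pytest.approx(classic, rel=1e-12)

    def test_matches_gls_oracle_ar1(self, rng):
        h = _random_instance(rng, 20)
        h.rho[:] = ar1(20, 0.7)
        est = ivw_correlated(h)
        omega = np.outer(h.se_Y, h.se_Y) * h.rho
        beta, cov = gls_oracle(h.b_X, h.b_Y, omega)
        assert est.theta == pytest.approx(float(beta[0]), rel=1e-10)
        resid = h.b_Y - est.theta * h.b_X
        oi = np.linalg.inv(omega)
        phi = max(1.0, np.sqrt(resid @ oi @ resid / (20 - 1)))
        assert est.se == pytest.approx(float(np.sqrt(cov[0, 0])) * phi, rel=1e-8)

    def test_random_effects_se_never_below_fixed(self, rng):
        for _ in range(20):
            h = _random_instance(rng, 8)
            est = ivw_correlated(h)
            assert est.method == "ivw_random" and est.phi >= 1.0
            omega = np.outer(h.se_Y, h.se_Y) * h.rho
            _, cov = gls_oracle(h.b_X, h.b_Y, omega)
            assert est.se >= np.sqrt(cov[0, 0]) - 1e-12

    def test_fixed_effects_for_three_or_fewer(self, rng):
        assert ivw_correlated(_random_instance(rng, 3)).method == "ivw_fixed"
        assert ivw_correlated(_random_instance(rng, 4)).method == "ivw_random"

    def test_near_singular_rho_is_shrunk_not_fatal(self):
        rho = np.array([[1.0, 1.0 - 1e-12], [1.0 - 1e-12, 1.0]])
        h = make_hset([0.1, 0.1], [0.02, 0.02], rho=rho)
        est = ivw_correlated(h)
        assert np.isfinite(est.theta) and np.isfinite(est.se)


class TestEggerCorrelated:
    def test_exact_proportional_fit(self):
        b_x = np.array([0.1, 0.2, 0.3, 0.4])
        h = make_hset(b_x, 0.5 * b_x)
        est = egger_correlated(h)
        assert est.theta == pytest.approx(0.5, abs=1e-10)
        assert est.intercept == pytest.approx(0.0, abs=1e-10)

    def test_affine_recovery(self):
        b_x = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        h = make_hset(b_x, 0.05 + 0.2 * b_x)
        est = egger_correlated(h)
        assert est.intercept == pytest.approx(0.05, abs=1e-10)
        assert est.theta == pytest.approx(0.2, abs=1e-10)

    def test_matches_whitening_oracle(self, rng):
        """Slope/intercept equal explicit WLS on the Cholesky-whitened system."""
        for _ in range(20):
            m = int(rng.integers(4, 25))
            h = _random_instance(rng, m)
            sign = np.where(h.b_X < 0, -1, 1)
            x, y = sign * h.b_X, sign * h.b_Y
            omega = np.outer(h.se_Y, h.se_Y) * h.rho
            L = np.linalg.cholesky(omega)
            Xw = np.linalg.solve(L, np.column_stack([np.ones(m), x]))
            yw = np.linalg.solve(L, y)
            coef, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
            est = egger_correlated(h)
            assert est.intercept == pytest.approx(float(coef[0]), rel=1e-8, abs=1e-12)
            assert est.theta == pytest.approx(float(coef[1]), rel=1e-8, abs=1e-12)

    def test_orientation_makes_exposure_nonnegative_and_theta_stable(self, rng):
        h = _random_instance(rng, 10)
        flipped = make_hset(-h.b_X, -h.b_Y, se_Y=h.se_Y, rho=h.rho)
        a, b = egger_correlated(h), egger_correlated(flipped)
        assert a.theta == pytest.approx(b.theta, rel=1e-12)

    def test_collinear_exposure_errors(self):
        h = make_hset([0.2, 0.2, 0.2], [0.1, 0.1, 0.1])
        with pytest.raises(np.linalg.LinAlgError):
            egger_correlated(h)

    def test_requires_three_variants(self, rng):
        with pytest.raises(ValueError):
            egger_correlated(_random_instance(rng, 2))


class TestPcaIvw:
    def test_full_variance_equals_fixed_ivw(self, rng):
        h = _random_instance(rng, 6)
        full = pca_ivw(h, variance_target=1.0)
        omega = np.outer(h.se_Y, h.se_Y) * h.rho
        beta, cov = gls_oracle(h.b_X, h.b_Y, omega)
        assert full.k_components == 6
        assert full.theta == pytest.approx(float(beta[0]), abs=1e-10)
        assert full.se == pytest.approx(float(np.sqrt(cov[0, 0])), abs=1e-10)

    def test_near_duplicate_variants_collapse_to_wald(self):
        rho = np.array([[1.0, 0.999], [0.999, 1.0]])
        h = make_hset([0.3, 0.3], [0.06, 0.06], se_Y=[0.02, 0.02], rho=rho)
        est = pca_ivw(h)
        single = wald_ratio(h.subset([0]))
        assert est.k_components == 1
        assert est.theta == pytest.approx(single.theta, abs=1e-3)

    def test_default_variance_target(self, rng):
        import inspect

        sig = inspect.signature(pca_ivw)
        assert sig.parameters["variance_target"].default == 0.99

    def test_component_count_recorded_and_reasonable(self, rng):
        h = _random_instance(rng, 12)
        h.rho[:] = ar1(12, 0.9)
        est = pca_ivw(h, variance_target=0.9)
        assert 1 <= est.k_components < 12


class TestSteiger:
    def test_strong_exposure_variant_retained(self):
        # |t_X| = 10 at n_X = 20,000 vs |t_Y| = 3 at n_Y = 400,000
        h = make_hset([0.1], [0.003], se_X=[0.01], se_Y=[0.001], n_X=20_000, n_Y=400_000)
        r2x = variance_explained(h.b_X, h.se_X, h.n_X)[0]
        r2y = variance_explained(h.b_Y, h.se_Y, h.n_Y)[0]
        assert r2x == pytest.approx(100 / (100 + 19_998), rel=1e-6)  # ~4.98e-3
        assert r2y == pytest.approx(9 / (9 + 399_998), rel=1e-6)  # ~2.25e-5
        kept, removed = steiger_filter(h)
        assert len(kept) == 1 and removed == []

    def test_exact_tie_retained(self):
        h = make_hset([0.1], [0.1], se_X=[0.01], se_Y=[0.01], n_X=1000, n_Y=1000)
        kept, removed = steiger_filter(h)
        assert len(kept) == 1 and removed == []

    def test_reverse_variant_removed_and_ivw_still_runs(self):
        b_x = np.array([0.10, 0.12, 0.002, 0.11])
        b_y = np.array([0.02, 0.024, 0.05, 0.022])
        h = make_hset(b_x, b_y, se_X=np.full(4, 0.01), se_Y=np.full(4, 0.005))
        kept, removed = steiger_filter(h)
        assert removed == ["v2"]
        est = estimate_auto(kept)
        assert np.isfinite(est.theta) and est.n_variants == 3

    def test_small_n_errors(self):
        h = make_hset([0.1], [0.1], n_X=2, n_Y=1000)
        with pytest.raises(ValueError):
            steiger_filter(h)


class TestEquivariance:
    @pytest.mark.parametrize("estimator", [ivw_correlated, egger_correlated, pca_ivw])
    def test_outcome_scale_equivariance(self, rng, estimator):
        """Multiplying b_Y and se_Y by c > 0 scales theta and se by c."""
        h = _random_instance(rng, 8)
        c = 3.7
        scaled = make_hset(h.b_X, c * h.b_Y, se_X=h.se_X, se_Y=c * h.se_Y, rho=h.rho)
        a, b = estimator(h), estimator(scaled)
        assert b.theta == pytest.approx(c * a.theta, rel=1e-9)
        assert b.se == pytest.approx(c * a.se, rel=1e-9)

    @pytest.mark.parametrize("estimator", [wald_ratio, ivw_correlated, pca_ivw])
    def test_outcome_sign_equivariance(self, rng, estimator):
        m = 1 if estimator is wald_ratio else 8
        h = _random_instance(rng, m)
        neg = make_hset(h.b_X, -h.b_Y, se_X=h.se_X, se_Y=h.se_Y, rho=h.rho)
        assert estimator(neg).theta == pytest.approx(-estimator(h).theta, rel=1e-9)

    def test_joint_variant_negation_leaves_ivw_unchanged(self, rng):
        h = _random_instance(rng, 6)
        s = np.ones(6)
        s[[1, 4]] = -1
        flipped = make_hset(
            s * h.b_X, s * h.b_Y, se_X=h.se_X, se_Y=h.se_Y, rho=np.outer(s, s) * h.rho
        )
        assert ivw_correlated(flipped).theta == pytest.approx(
            ivw_correlated(h).theta, rel=1e-9
        )
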
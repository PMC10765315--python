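"""Causal estimators for correlated cis instruments.

All estimators consume a :class:`~targetmr.sumstats_io.HarmonizedSet` and
return an :class:`MREstimate` whose ``theta`` is the causal effect per SD
increase in genetically predicted protein level (log-odds scale when the
outcome is binary).

The multi-variant estimators are generalized-least-squares fits that adjust
for the between-variant correlation structure rho through the outcome-error
covariance

    Omega_ij = se_Y,i * se_Y,j * rho_ij.

Fixed effects are used for 2-3 variants and multiplicative random effects
(residual scale phi, floored at 1) for more than 3, mirroring common
drug-target MR practice.  MR-Egger adds an intercept absorbing directional
horizontal pleiotropy; principal-components IVW replaces the variants by the
leading eigenvectors of the weighted LD structure (99% of variance by
default), which stabilises the fit when variants are strongly correlated.
Steiger filtering removes variants explaining more variance in the outcome
than in the exposure, guarding against reverse causation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from .sumstats_io import HarmonizedSet

logger = logging.getLogger("targetmr")

#: condition-number ceiling beyond which rho is shrunk toward the identity
_COND_MAX = 1e8
#: shrinkage levels tried in order: (1 - lam) * rho + lam * I
_SHRINKAGE_LEVELS = (0.0, 1e-6, 1e-3)


class ConditioningError(np.linalg.LinAlgError):
    """Omega numerically singular even after shrinkage; advises stricter r2."""


@dataclass(frozen=True)
class MREstimate:
    """A causal estimate with its uncertainty and method metadata."""

    method: str  # wald | ivw_fixed | ivw_random | egger | pca_ivw
    theta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_variants: int
    phi: float = 1.0
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    k_components: int | None = None

    @property
    def odds_ratio(self) -> float:
        """exp(theta): odds ratio per SD when theta is on the log-odds scale."""
        return float(np.exp(self.theta))

    @property
    def odds_ratio_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))


def _normal_ci_p(theta: float, se: float) -> tuple[float, float, float]:
    z = stats.norm.ppf(0.975)
    p = float(np.clip(2.0 * stats.norm.sf(abs(theta) / se), np.nextafter(0, 1), 1.0))
    return theta - z * se, theta + z * se, p


def _omega(hset: HarmonizedSet) -> np.ndarray:
    """Outcome-error covariance, shrinking rho toward I if ill-conditioned."""
    for lam in _SHRINKAGE_LEVELS:
        rho = (1 - lam) * hset.rho + lam * np.eye(len(hset))
        omega = np.outer(hset.se_Y, hset.se_Y) * rho
        if np.linalg.cond(omega) <= _COND_MAX:
            if lam > 0:
                logger.info("Omega ill-conditioned; shrunk rho with lambda=%g", lam)
            return omega
    raise ConditioningError(
        "Omega is numerically singular even after shrinkage; "
        "consider a stricter r2 clumping threshold"
    )


def _gls(X: np.ndarray, y: np.ndarray, omega: np.ndarray):
    """Solve the GLS normal equations via Cholesky whitening.

    Returns coefficient vector, unscaled covariance, and whitened residuals.
    """
    c, low = linalg.cho_factor(omega)
    Xw = linalg.cho_solve((c, low), X)
    xtx_inv = np.linalg.inv(X.T @ Xw)
    beta = xtx_inv @ (Xw.T @ y)
    resid = y - X @ beta
    resid_w = linalg.cho_solve((c, low), resid)
    return beta, xtx_inv, float(resid @ resid_w)


def wald_ratio(hset: HarmonizedSet) -> MREstimate:
    """Single-variant causal estimate: theta = b_Y / b_X, se = se_Y / |b_X|.

    First-order delta method (exposure uncertainty ignored, as usual for
    strong single instruments); normal CI and p.
    """
    if len(hset) != 1:
        raise ValueError(f"wald_ratio requires exactly 1 variant, got {len(hset)}")
    b_x, b_y, se_y = hset.b_X[0], hset.b_Y[0], hset.se_Y[0]
    if b_x == 0:
        raise ZeroDivisionError("undefined Wald ratio: exposure effect is zero")
    theta = b_y / b_x
    se = se_y / abs(b_x)
    lo, hi, p = _normal_ci_p(theta, se)
    return MREstimate("wald", float(theta), float(se), lo, hi, p, 1)


def ivw_correlated(hset: HarmonizedSet) -> MREstimate:
    """Correlation-adjusted IVW: fixed effects for 2-3 variants,
    multiplicative random effects (phi floored at 1) for more than 3."""
    j = len(hset)
    if j < 2:
        raise ValueError(f"ivw_correlated requires >= 2 variants, got {j}")
    omega = _omega(hset)
    X = hset.b_X[:, None]
    beta, cov, rss = _gls(X, hset.b_Y, omega)
    theta = float(beta[0])
    base_se = float(np.sqrt(cov[0, 0]))
    if j > 3:
        phi = max(1.0, float(np.sqrt(rss / (j - 1))))
        method = "ivw_random"
    else:
        phi = 1.0
        method = "ivw_fixed"
    se = base_se * phi
    lo, hi, p = _normal_ci_p(theta, se)
    return MREstimate(method, theta, se, lo, hi, p, j, phi=phi)


def egger_correlated(hset: HarmonizedSet, floor_phi: bool = False) -> MREstimate:
    """Correlation-adjusted MR-Egger: GLS of b_Y on [1, b_X] with each
    variant oriented so b_X >= 0.

    Joint negation of a variant's (b_X, b_Y) leaves the Wald-numerator
    correlation structure unchanged, so rho is not modified.  Inference uses
    the t distribution with J-2 df and the estimated multiplicative residual
    scale, i.e. ordinary weighted-regression inference, which keeps the
    intercept (pleiotropy) test calibrated at small J.  Set ``floor_phi``
    for the conservative variant that never deflates the standard errors
    below the fixed-effect ones.
    """
    j = len(hset)
    if j < 3:
        raise ValueError(f"egger_correlated requires >= 3 variants, got {j}")
    sign = np.where(hset.b_X < 0, -1.0, 1.0)
    x = sign * hset.b_X
    y = sign * hset.b_Y
    if np.allclose(x, x[0]):
        raise np.linalg.LinAlgError("all exposure effects equal after orientation")
    omega = _omega(hset)
    X = np.column_stack([np.ones(j), x])
    beta, cov, rss = _gls(X, y, omega)
    phi = float(np.sqrt(rss / (j - 2)))
    if floor_phi:
        phi = max(1.0, phi)
    ses = phi * np.sqrt(np.diag(cov))
    tcrit = stats.t.ppf(0.975, df=j - 2)
    p_slope = float(np.clip(2 * stats.t.sf(abs(beta[1]) / ses[1], df=j - 2),
                            np.nextafter(0, 1), 1.0))
    p_int = float(np.clip(2 * stats.t.sf(abs(beta[0]) / ses[0], df=j - 2),
                          np.nextafter(0, 1), 1.0))
    return MREstimate(
        "egger",
        theta=float(beta[1]),
        se=float(ses[1]),
        ci_low=float(beta[1] - tcrit * ses[1]),
        ci_high=float(beta[1] + tcrit * ses[1]),
        p=p_slope,
        n_variants=j,
        phi=phi,
        intercept=float(beta[0]),
        intercept_se=float(ses[0]),
        intercept_p=p_int,
    )


def pca_ivw(hset: HarmonizedSet, variance_target: float = 0.99) -> MREstimate:
    """Principal-components IVW on the leading eigenvectors of the weighted
    LD structure Phi_ij = b_X,i b_X,j rho_ij / (se_Y,i se_Y,j).

    The smallest k whose eigenvalues cover ``variance_target`` of the trace
    (default 99%) defines the projection; a fixed-effect GLS-IVW is run in
    the projected space.
    """
    j = len(hset)
    if j < 2:
        raise ValueError(f"pca_ivw requires >= 2 variants, got {j}")
    if not (0 < variance_target <= 1):
        raise ValueError("variance_target must be in (0, 1]")
    w = hset.b_X / hset.se_Y
    phi_mat = np.outer(w, w) * hset.rho
    evals, evecs = np.linalg.eigh(phi_mat)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    evals = np.clip(evals, 0.0, None)
    total = evals.sum()
    if total <= 0:
        raise np.linalg.LinAlgError("weighted LD structure has no positive eigenvalues")
    frac = np.cumsum(evals) / total
    k = int(np.searchsorted(frac, variance_target - 1e-12) + 1)
    V = evecs[:, :k]
    omega = _omega(hset)
    bx = V.T @ hset.b_X
    by = V.T @ hset.b_Y
    omega_p = V.T @ omega @ V
    c, low = linalg.cho_factor(omega_p)
    bxw = linalg.cho_solve((c, low), bx)
    prec = float(bx @ bxw)
    theta = float(bxw @ by) / prec
    se = float(np.sqrt(1.0 / prec))
    lo, hi, p = _normal_ci_p(theta, se)
    return MREstimate("pca_ivw", theta, se, lo, hi, p, j, k_components=k)


def variance_explained(beta: np.ndarray, se: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Per-variant variance explained from the t statistic: t^2/(t^2 + n - 2)."""
    n = np.asarray(n, dtype=float)
    if np.any(n <= 2):
        raise ValueError("sample sizes must exceed 2 for variance explained")
    t2 = (np.asarray(beta) / np.asarray(se)) ** 2
    return t2 / (t2 + n - 2)


def steiger_filter(hset: HarmonizedSet) -> tuple[HarmonizedSet, list[str]]:
    """Remove variants explaining strictly more variance in the outcome than
    in the exposure; ties are retained."""
    r2_x = variance_explained(hset.b_X, hset.se_X, hset.n_X)
    r2_y = variance_explained(hset.b_Y, hset.se_Y, hset.n_Y)
    keep = np.flatnonzero(~(r2_y > r2_x))
    removed = [hset.variant_ids[i] for i in range(len(hset)) if i not in set(keep)]
    if removed:
        logger.info("steiger_filter removed %d variant(s): %s", len(removed), removed)
    return hset.subset(keep), removed


def estimate_auto(hset: HarmonizedSet) -> MREstimate:
    """Primary-analysis estimator selection: Wald ratio for a single variant,
    otherwise correlation-adjusted IVW (fixed for 2-3, random for >3)."""
    if len(hset) == 0:
        raise ValueError("cannot estimate on an empty instrument")
    if len(hset) == 1:
        return wald_ratio(hset)
    return ivw_correlated(hset)
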
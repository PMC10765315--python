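"""Colocalization by per-variant approximate Bayes factors (enumeration).

Under a single-causal-variant assumption per trait, the five hypotheses for
a region are: H0 no association, H1/H2 association with one trait only,
H3 two distinct causal variants, H4 one shared causal variant.  Posterior
probabilities PP0..PP4 are computed by summing per-variant Wakefield
approximate Bayes factors in log space and weighting by per-variant priors.
PP(H4) > 0.80 is the usual convention for strong evidence of a shared
causal variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .sumstats_io import HarmonizedSet


@dataclass(frozen=True)
class ColocPriors:
    """Per-variant priors and prior effect variances.

    ``p1``/``p2`` are the priors for association with trait 1/2 only,
    ``p12`` for a shared association.  ``w1``/``w2`` are the prior effect
    variances; the defaults correspond to prior SD 0.2 for a quantitative
    trait (protein, per-SD scale) and 0.15 for a binary trait (log-odds).
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    w1: float = 0.2**2
    w2: float = 0.15**2

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p12"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ValueError("p1 + p2 + p12 must be < 1")
        if self.w1 <= 0 or self.w2 <= 0:
            raise ValueError("prior effect variances must be > 0")


@dataclass(frozen=True)
class ColocResult:
    pp: tuple[float, float, float, float, float]  # PP0..PP4
    n_variants: int
    priors: ColocPriors

    @property
    def pp4(self) -> float:
        return self.pp[4]


def wakefield_log_abf(beta, se, w: float):
    """Log approximate Bayes factor for one association.

    With V = se^2, z = beta/se and shrinkage r = w/(w+V):
    log ABF = 0.5*log(1-r) + 0.5*r*z^2.  Positive values favour association.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    if w <= 0:
        raise ValueError("prior variance w must be > 0")
    v = se**2
    r = w / (w + v)
    z = beta / se
    out = 0.5 * np.log1p(-r) + 0.5 * r * z**2
    return float(out) if out.ndim == 0 else out


def coloc_posteriors(
    hset: HarmonizedSet, priors: ColocPriors = ColocPriors()
) -> ColocResult:
    """Enumeration posteriors PP0..PP4 over the harmonized region.

    Hypothesis sums are accumulated in log space: H1 over trait-1 ABFs, H2
    over trait-2, H3 over ordered distinct variant pairs, H4 over shared
    variants.  With a single variant H3 is impossible and PP3 = 0.
    """
    m = len(hset)
    if m < 1:
        raise ValueError("coloc requires at least one variant")
    l1 = wakefield_log_abf(hset.b_X, hset.se_X, priors.w1)
    l2 = wakefield_log_abf(hset.b_Y, hset.se_Y, priors.w2)
    l1 = np.atleast_1d(l1)
    l2 = np.atleast_1d(l2)
    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    # sum over ordered distinct pairs = (sum_i e^l1_i)(sum_j e^l2_j) - sum_i e^(l1_i+l2_i)
    log_h = np.empty(5)
    log_h[0] = 0.0
    log_h[1] = np.log(priors.p1) + s1
    log_h[2] = np.log(priors.p2) + s2
    pair_total = s1 + s2
    if m == 1 or pair_total <= s12:  # single variant, or numerically degenerate
        log_h[3] = -np.inf
    else:
        log_h[3] = (
            np.log(priors.p1) + np.log(priors.p2)
            + pair_total + np.log1p(-np.exp(s12 - pair_total))
        )
    log_h[4] = np.log(priors.p12) + s12
    pp = np.exp(log_h - logsumexp(log_h))
    pp = pp / pp.sum()
    return ColocResult(tuple(float(x) for x in pp), m, priors)
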
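"""Orchestration: primary analyses with FDR control, the sensitivity
battery, the robustness verdict, reverse-direction MR and the phenome-wide
scan with beneficial/adverse classification.

The primary analysis estimates, per protein-outcome pair, the effect per SD
of genetically predicted protein on the outcome (Wald ratio for a single
variant, correlation-adjusted IVW otherwise), applies Steiger filtering,
and flags pairs significant at Benjamini-Hochberg FDR-adjusted p < 0.05.
A finding is graded *robust* when (1) the primary analysis is significant,
(2) every sensitivity analysis is directionally consistent with it, and
(3) reverse-direction MR shows no evidence of reverse causation
(unadjusted p > 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .instruments import Instrument, InstrumentSpec, select_instruments
from .mr_core import (
    MREstimate,
    egger_correlated,
    estimate_auto,
    pca_ivw,
    steiger_filter,
)
from .sumstats_io import HarmonizedSet

logger = logging.getLogger("targetmr")

#: r2 grid of the sensitivity battery (the primary 0.4 is not repeated)
R2_GRID = (0.001, 0.01, 0.1, 0.2, 0.6, 0.8)
#: stricter instrument p-value grid of the sensitivity battery
P_GRID = (1e-6, 5e-8)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _estimate_row(protein: str, outcome: str, inst: Instrument, est: MREstimate) -> dict:
    return {
        "protein": protein,
        "outcome": outcome,
        "method": est.method,
        "theta": est.theta,
        "se": est.se,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "p": est.p,
        "n_variants": est.n_variants,
        "phi": est.phi,
        "intercept": est.intercept,
        "intercept_se": est.intercept_se,
        "intercept_p": est.intercept_p,
        "k_components": est.k_components,
        "f_stat": inst.f_stat,
        "odds_ratio": est.odds_ratio,
    }


def run_primary(
    datasets: Mapping[tuple[str, str], HarmonizedSet],
    spec: InstrumentSpec = InstrumentSpec(),
    pool_outcomes: bool = True,
    alpha: float = 0.05,
    steiger: bool = True,
) -> pd.DataFrame:
    """Primary MR over all protein-outcome pairs with BH-FDR flags.

    ``datasets`` maps (protein, outcome) to the full harmonized cis region.
    Pairs with no instrument are excluded (logged).  FDR is applied over the
    pooled set of tests by default; ``pool_outcomes=False`` adjusts within
    each outcome separately.  Steiger filtering is applied before the
    estimator-selection rule counts variants.
    """
    rows = []
    for (protein, outcome), hset in datasets.items():
        inst = select_instruments(hset, spec)
        if inst is None:
            logger.info("run_primary: %s/%s has no instrument, excluded", protein, outcome)
            continue
        kept = inst.harmonized
        if steiger:
            kept, removed = steiger_filter(kept)
            if len(kept) == 0:
                logger.info("run_primary: %s/%s emptied by Steiger filtering", protein, outcome)
                continue
        est = estimate_auto(kept)
        rows.append(_estimate_row(protein, outcome, inst, est))
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    if pool_outcomes:
        df["p_fdr"] = bh_fdr(df["p"].to_numpy())
    else:
        df["p_fdr"] = df.groupby("outcome")["p"].transform(lambda s: bh_fdr(s.to_numpy()))
    df["significant"] = df["p_fdr"] < alpha
    return df


# ---------------------------------------------------------------------------
# sensitivity battery and robustness verdict
# ---------------------------------------------------------------------------


@dataclass
class SensitivityProfile:
    """Primary estimate plus the full sensitivity grid for one pair."""

    protein: str
    outcome: str
    primary: MREstimate
    primary_significant: bool
    grid: list[tuple[str, MREstimate]]
    reverse_p: float | None = None
    verdict: str | None = None
    flags: dict = field(default_factory=dict)


def run_sensitivity_battery(
    hset: HarmonizedSet,
    spec: InstrumentSpec = InstrumentSpec(),
    protein: str = "protein",
    outcome: str = "outcome",
    primary_significant: bool = True,
    reverse_hset: HarmonizedSet | None = None,
    r2_grid: Sequence[float] = R2_GRID,
    p_grid: Sequence[float] = P_GRID,
    variance_target: float = 0.99,
) -> SensitivityProfile:
    """Re-select and re-estimate across the sensitivity grid.

    The full battery comprises the r2 grid, the stricter instrument-p grid,
    PCA-IVW and MR-Egger on the primary instrument (10 analyses when every
    grid point yields an instrument; empty grid points are omitted and
    logged).  Reverse-direction MR uses caller-supplied instruments for the
    outcome (e.g. genome-wide significant HDP loci) harmonized against the
    protein; its unadjusted p feeds the robustness verdict.
    """
    primary_inst = select_instruments(hset, spec)
    if primary_inst is None:
        raise ValueError("no primary instrument; battery undefined")
    primary = estimate_auto(primary_inst.harmonized)
    grid: list[tuple[str, MREstimate]] = []
    phset = primary_inst.harmonized

    if len(phset) >= 2:
        grid.append(("pca", pca_ivw(phset, variance_target)))
    else:
        logger.info("sensitivity: PCA-IVW omitted (<2 variants)")
    if len(phset) >= 3:
        grid.append(("egger", egger_correlated(phset)))
    else:
        logger.info("sensitivity: Egger omitted (<3 variants)")

    for r2 in r2_grid:
        inst = select_instruments(hset, InstrumentSpec(spec.p_threshold, r2))
        if inst is None:
            logger.info("sensitivity: r2<%g grid point empty, omitted", r2)
            continue
        grid.append((f"r2<{r2:g}", estimate_auto(inst.harmonized)))
    for pt in p_grid:
        inst = select_instruments(hset, InstrumentSpec(pt, spec.r2_threshold))
        if inst is None:
            logger.info("sensitivity: p<%g grid point empty, omitted", pt)
            continue
        grid.append((f"p<{pt:g}", estimate_auto(inst.harmonized)))

    reverse_p = None
    if reverse_hset is not None:
        reverse_p = estimate_auto(reverse_hset).p

    profile = SensitivityProfile(
        protein=protein,
        outcome=outcome,
        primary=primary,
        primary_significant=primary_significant,
        grid=grid,
        reverse_p=reverse_p,
    )
    assess_robustness(profile)
    return profile


def assess_robustness(profile: SensitivityProfile) -> str:
    """Three-criterion verdict, stored on the profile and returned.

    Robust iff the primary analysis is significant, every sensitivity
    estimate shares the primary's sign, and reverse-direction MR gives
    unadjusted p > 0.05 (absent reverse MR counts as no evidence).
    """
    c1 = bool(profile.primary_significant)
    primary_sign = np.sign(profile.primary.theta)
    c2 = all(np.sign(est.theta) == primary_sign for _, est in profile.grid)
    c3 = profile.reverse_p is None or profile.reverse_p > 0.05
    profile.flags = {
        "primary_significant": c1,
        "directionally_consistent": c2,
        "no_reverse_causation": c3,
    }
    profile.verdict = "robust" if (c1 and c2 and c3) else "not_robust"
    return profile.verdict


def profile_to_frame(profile: SensitivityProfile) -> pd.DataFrame:
    """Flatten a sensitivity profile into the Fig-2-style long table."""
    rows = [("primary", profile.primary)] + profile.grid
    df = pd.DataFrame(
        {
            "protein": profile.protein,
            "outcome": profile.outcome,
            "analysis": label,
            "method": est.method,
            "theta": est.theta,
            "se": est.se,
            "ci_low": est.ci_low,
            "ci_high": est.ci_high,
            "p": est.p,
            "n_variants": est.n_variants,
        }
        for label, est in rows
    )
    df.attrs["verdict"] = profile.verdict
    return df


# ---------------------------------------------------------------------------
# phenome-wide scan
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhewasResult:
    protein: str
    phenotype: str
    theta: float
    se: float
    p: float
    significant: bool
    direction_class: str | None  # beneficial | adverse; None unless significant


def phenomewide_scan(
    protein: str,
    hdp_protective_sign: int,
    phenotypes: Mapping[str, HarmonizedSet],
    n_proteins: int,
    alpha: float = 0.05,
    spec: InstrumentSpec | None = None,
) -> list[PhewasResult]:
    """Scan one protein's instrument across disease phenotypes.

    ``hdp_protective_sign`` is +1 if *higher* protein lowers HDP risk and -1
    if lower protein does.  Significance uses the Bonferroni-style lenient
    threshold alpha / n_proteins.  A significant association is *beneficial*
    when the HDP-risk-lowering direction of the protein also lowers the
    phenotype's risk, *adverse* otherwise.
    """
    if hdp_protective_sign not in (-1, 1):
        raise ValueError("hdp_protective_sign must be +1 or -1")
    threshold = alpha / n_proteins
    results = []
    for name, hset in phenotypes.items():
        if spec is not None:
            inst = select_instruments(hset, spec)
            if inst is None:
                logger.info("phewas: %s/%s has no instrument, skipped", protein, name)
                continue
            hset = inst.harmonized
        if len(hset) == 0:
            logger.info("phewas: %s/%s has no overlapping variants, skipped", protein, name)
            continue
        est = estimate_auto(hset)
        significant = est.p < threshold
        direction = None
        if significant:
            direction = "beneficial" if hdp_protective_sign * est.theta < 0 else "adverse"
        results.append(
            PhewasResult(protein, name, est.theta, est.se, est.p, significant, direction)
        )
    return results


def phewas_to_frame(results: Sequence[PhewasResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
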
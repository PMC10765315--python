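"""Synthetic GWAS summary statistics and observational study tables.

The region simulator emulates the two-sample setting the estimators assume:
a cis region of ``m_variants`` variants with AR(1) LD (rho_ij = c^|i-j|),
a sparse set of true pQTL effects gamma on the protein, an optional causal
protein effect ``theta`` on the outcome, and optional direct (pleiotropic)
variant effects alpha.  Effects are on the standardized-genotype,
standardized-trait scale, so marginal standard errors are 1/sqrt(n) and the
marginal effect means are rho @ gamma (exposure) and
rho @ (theta*gamma + alpha) (outcome), with sampling noise MVN(0, rho/n).
Allele frequencies play no role on this scale; EAF is emitted as a 0.5
placeholder and alleles as a fixed non-palindromic A/G pair.

The observational-study simulator emulates a systematic-review table:
per-study log10 mean ratios (HDP vs non-HDP) that drift linearly with
gestational week, with noise shrinking as study size grows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from .gestation_meta import StudyTimepoint
from .sumstats_io import HarmonizedSet, LDMatrix, VariantAssoc

_POS0 = 1_000_000
_SPACING = 1_000  # bp between synthetic variants


@dataclass(frozen=True)
class SimConfig:
    """Region-simulation parameters.

    Defaults reflect a typical well-powered cis-pQTL instrument: a 50-variant
    region with moderately strong local LD (c = 0.7 at 1 kb spacing), three
    true pQTLs of SD 0.15 per allele, a protein GWAS of 20,000 and an outcome
    GWAS of 300,000, causal effect 0.1 per SD of protein, no pleiotropy.
    """

    m_variants: int = 50
    ld_decay: float = 0.7
    n_causal: int = 3
    tau: float = 0.15
    theta: float = 0.1
    pleio_sd: float = 0.0
    n_x: int = 20_000
    n_y: int = 300_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.m_variants >= self.n_causal >= 0):
            raise ValueError("need m_variants >= n_causal >= 0")
        if not (0 <= self.ld_decay < 1):
            raise ValueError("ld_decay must be in [0, 1)")
        if self.n_x < 10 or self.n_y < 10:
            raise ValueError("sample sizes must be >= 10")

    def replicate(self, i: int) -> "SimConfig":
        """Substream config for replicate ``i`` (seed + replicate index)."""
        return replace(self, seed=int(self.seed + i))


@dataclass
class TruthRecord:
    """Ground truth behind one simulated region (JSON-serializable)."""

    gamma: list[float]  # full-length true pQTL effect vector
    alpha: list[float]  # full-length direct (pleiotropic) outcome effects
    theta: float
    causal_idx: list[int]
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        return cls(**json.loads(Path(path).read_text()))


def _variant_ids(m: int) -> list[str]:
    return [f"sv{i:04d}" for i in range(m)]


def simulate_ld(m: int, c: float) -> LDMatrix:
    """AR(1) correlation rho_ij = c^|i-j| over m synthetic variants."""
    if not (0 <= c < 1):
        raise ValueError("decay c must be in [0, 1)")
    idx = np.arange(m)
    r = c ** np.abs(idx[:, None] - idx[None, :]) if m else np.empty((0, 0))
    return LDMatrix(tuple(_variant_ids(m)), r)


def _assoc_list(beta: np.ndarray, se: float, n: int) -> list[VariantAssoc]:
    z = beta / se
    p = np.clip(2 * stats.norm.sf(np.abs(z)), np.nextafter(0, 1), 1.0)
    return [
        VariantAssoc(
            variant_id=f"sv{i:04d}",
            chrom="1",
            pos=_POS0 + i * _SPACING,
            effect_allele="A",
            other_allele="G",
            eaf=0.5,  # placeholder: synthetic standardized-scale data
            beta=float(beta[i]),
            se=float(se),
            p=float(p[i]),
            n=n,
        )
        for i in range(len(beta))
    ]


def simulate_region_sumstats(
    cfg: SimConfig,
) -> tuple[list[VariantAssoc], list[VariantAssoc], LDMatrix, TruthRecord]:
    """Draw one region's exposure and outcome marginal summary statistics.

    Fully reproducible from ``cfg.seed``; the returned truth record stores
    the drawn gamma, alpha, theta and seed.
    """
    rng = np.random.default_rng(cfg.seed)
    m = cfg.m_variants
    ld = simulate_ld(m, cfg.ld_decay)
    rho = ld.r
    chol = np.linalg.cholesky(rho + 1e-12 * np.eye(m)) if m else np.empty((0, 0))

    causal = np.sort(rng.choice(m, size=cfg.n_causal, replace=False)) if cfg.n_causal else np.array([], dtype=int)
    gamma = np.zeros(m)
    gamma[causal] = rng.normal(0.0, cfg.tau, size=cfg.n_causal)
    alpha = np.zeros(m)
    if cfg.pleio_sd > 0:
        alpha[causal] = rng.normal(0.0, cfg.pleio_sd, size=cfg.n_causal)

    se_x = 1.0 / np.sqrt(cfg.n_x)
    se_y = 1.0 / np.sqrt(cfg.n_y)
    b_x = rho @ gamma + se_x * (chol @ rng.standard_normal(m))
    b_y = rho @ (cfg.theta * gamma + alpha) + se_y * (chol @ rng.standard_normal(m))

    truth = TruthRecord(
        gamma=gamma.tolist(),
        alpha=alpha.tolist(),
        theta=cfg.theta,
        causal_idx=causal.tolist(),
        seed=cfg.seed,
    )
    return _assoc_list(b_x, se_x, cfg.n_x), _assoc_list(b_y, se_y, cfg.n_y), ld, truth


def simulate_harmonized(cfg: SimConfig) -> tuple[HarmonizedSet, TruthRecord]:
    """Convenience: simulate a region and return it as a HarmonizedSet."""
    from .sumstats_io import harmonize

    exp, out, ld, truth = simulate_region_sumstats(cfg)
    return harmonize(exp, out, ld, drop_palindromic=False), truth


def simulate_observational_studies(
    n_studies: int,
    true_slope: float = 0.039,
    noise_sd: float = 0.15,
    seed: int = 0,
    intercept: float = -0.8,
    protein: str = "NT-proBNP",
    hdp_subtype: str = "preeclampsia",
) -> list[StudyTimepoint]:
    """Synthetic systematic-review table with a known per-week trend.

    Gestational weeks are uniform on [6, 40]; the study-level log10 mean
    ratio is intercept + true_slope*week plus Normal(0, noise_sd/sqrt(n/100))
    noise, so larger studies are tighter.  Group means are back-computed from
    the ratio with the control mean fixed at 100 arbitrary units.  The
    default slope/intercept place the zero-crossing in mid-gestation, the
    pattern seen for natriuretic peptides in hypertensive pregnancy.
    """
    if n_studies < 2:
        raise ValueError("need at least 2 studies")
    rng = np.random.default_rng(seed)
    weeks = rng.uniform(6.0, 40.0, size=n_studies)
    n_hdp = rng.integers(10, 200, size=n_studies)
    n_ctrl = rng.integers(20, 400, size=n_studies)
    total = n_hdp + n_ctrl
    ratio = intercept + true_slope * weeks
    ratio = ratio + rng.normal(0.0, 1.0, size=n_studies) * noise_sd / np.sqrt(total / 100.0)
    return [
        StudyTimepoint(
            study_id=f"study{i:03d}",
            protein=protein,
            hdp_subtype=hdp_subtype,
            gest_week=float(weeks[i]),
            mean_hdp=float(100.0 * 10.0 ** ratio[i]),
            mean_ctrl=100.0,
            n_hdp=int(n_hdp[i]),
            n_ctrl=int(n_ctrl[i]),
        )
        for i in range(n_studies)
    ]
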
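"""Gestational-trend meta-regression over study-level biomarker data.

Each study contributes, at one gestational week, the mean protein
concentration in the hypertensive-pregnancy (HDP) group and in the
normotensive group.  The contrast is the base-10 log of the mean ratio
(HDP / non-HDP), and the trend across gestation is a weighted least-squares
regression of that log-ratio on gestational week, weighted by each study's
total sample size, with t-based inference (df = n_points - 2).  Studies
labelled "mixed" (HDP subtype not distinguished) are excluded from
subtype-specific fits by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger("targetmr")

HDP_SUBTYPES = ("preeclampsia", "gestational hypertension", "mixed")


@dataclass(frozen=True)
class StudyTimepoint:
    """One study's group means at one gestational sampling week."""

    study_id: str
    protein: str
    hdp_subtype: str
    gest_week: float
    mean_hdp: float
    mean_ctrl: float
    n_hdp: int
    n_ctrl: int
    reports_median: bool = False  # medians pooled as approximate means

    def __post_init__(self) -> None:
        if self.mean_hdp <= 0 or self.mean_ctrl <= 0:
            raise ValueError("group mean concentrations must be > 0")
        if not (0 < self.gest_week < 45):
            raise ValueError(f"gest_week must be in (0, 45), got {self.gest_week}")
        if self.n_hdp < 1 or self.n_ctrl < 1:
            raise ValueError("group sizes must be >= 1")
        if self.hdp_subtype not in HDP_SUBTYPES:
            raise ValueError(f"unknown hdp_subtype {self.hdp_subtype!r}")
        if self.reports_median:
            logger.info("study %s pools a median as an approximate mean", self.study_id)

    @property
    def weight(self) -> int:
        return self.n_hdp + self.n_ctrl


@dataclass(frozen=True)
class TrendFit:
    """Fitted per-week trend in the log10 HDP/non-HDP mean ratio."""

    protein: str
    hdp_subtype: str
    slope: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    intercept: float
    n_points: int
    quad_coef: float | None = None
    quad_p: float | None = None


def log_ratio(tp: StudyTimepoint) -> float:
    """log10(mean_hdp / mean_ctrl); antisymmetric under group swap."""
    return float(np.log10(tp.mean_hdp / tp.mean_ctrl))


def fit_weighted_trend(
    points: Sequence[StudyTimepoint],
    include_mixed: bool = False,
    quadratic: bool = False,
) -> TrendFit:
    """Sample-size-weighted regression of log10 mean ratio on gestational week.

    Weights are each study's total sample size (n_hdp + n_ctrl), defined up
    to proportionality.  Inference uses the t distribution with
    n_points - 2 df (n_points - 3 with the optional quadratic term); at
    least 3 points are required for a reported p-value.
    """
    pts = [p for p in points if include_mixed or p.hdp_subtype != "mixed"]
    if len(pts) < 2:
        raise ValueError("need >= 2 study timepoints to fit a trend")
    proteins = {p.protein for p in pts}
    if len(proteins) > 1:
        raise ValueError(f"timepoints span multiple proteins: {sorted(proteins)}")
    weeks = np.array([p.gest_week for p in pts])
    if np.ptp(weeks) == 0:
        raise np.linalg.LinAlgError("all timepoints at a single gestational week")
    y = np.array([log_ratio(p) for p in pts])
    w = np.array([p.weight for p in pts], dtype=float)
    cols = [np.ones_like(weeks), weeks]
    if quadratic:
        cols.append(weeks**2)
    X = np.column_stack(cols)
    with np.errstate(divide="ignore", invalid="ignore"):  # saturated 2-point fit
        res = sm.WLS(y, X, weights=w).fit()
        ci = res.conf_int()
    subtypes = {p.hdp_subtype for p in pts}
    subtype = subtypes.pop() if len(subtypes) == 1 else "mixed"
    enough = len(pts) >= (4 if quadratic else 3)
    return TrendFit(
        protein=proteins.pop(),
        hdp_subtype=subtype,
        slope=float(res.params[1]),
        se=float(res.bse[1]),
        ci_low=float(ci[1, 0]),
        ci_high=float(ci[1, 1]),
        p=float(res.pvalues[1]) if enough else float("nan"),
        intercept=float(res.params[0]),
        n_points=len(pts),
        quad_coef=float(res.params[2]) if quadratic else None,
        quad_p=float(res.pvalues[2]) if quadratic and enough else None,
    )


# ---------------------------------------------------------------------------
# tabular I/O and plotting
# ---------------------------------------------------------------------------

_COLUMNS = (
    "study_id", "protein", "hdp_subtype", "gest_week",
    "mean_hdp", "mean_ctrl", "n_hdp", "n_ctrl",
)


def read_study_table(path) -> list[StudyTimepoint]:
    """Read a StudyTimepoint TSV (columns as in ``_COLUMNS``)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"study table missing columns: {sorted(missing)}")
    return [
        StudyTimepoint(
            study_id=str(r.study_id),
            protein=str(r.protein),
            hdp_subtype=str(r.hdp_subtype),
            gest_week=float(r.gest_week),
            mean_hdp=float(r.mean_hdp),
            mean_ctrl=float(r.mean_ctrl),
            n_hdp=int(r.n_hdp),
            n_ctrl=int(r.n_ctrl),
            reports_median=bool(getattr(r, "reports_median", False)),
        )
        for r in df.itertuples(index=False)
    ]


def write_study_table(points: Iterable[StudyTimepoint], path) -> None:
    pd.DataFrame([
        {c: getattr(p, c) for c in _COLUMNS} | {"reports_median": p.reports_median}
        for p in points
    ]).to_csv(path, sep="\t", index=False)


def trend_to_frame(fits: Iterable[TrendFit]) -> pd.DataFrame:
    return pd.DataFrame([vars(f) for f in fits])


def plot_trend(points: Sequence[StudyTimepoint], fit: TrendFit, path) -> None:
    """Week vs log-ratio scatter (point area ~ study size) with the fit line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pts = [p for p in points if p.hdp_subtype == fit.hdp_subtype]
    weeks = np.array([p.gest_week for p in pts])
    y = np.array([log_ratio(p) for p in pts])
    w = np.array([p.weight for p in pts], dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(weeks, y, s=20 + 180 * w / w.max(), alpha=0.6, edgecolor="k")
    grid = np.linspace(weeks.min(), weeks.max(), 50)
    ax.plot(grid, fit.intercept + fit.slope * grid, color="firebrick")
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel("Gestational age at sampling (weeks)")
    ax.set_ylabel("log10 mean ratio (HDP / non-HDP)")
    ax.set_title(f"{fit.protein} ({fit.hdp_subtype})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
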
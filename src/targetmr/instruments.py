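"""Genetic-instrument construction: p-value filtering, greedy LD clumping,
and instrument strength.

An instrument is the set of largely uncorrelated cis-pQTLs surviving the
p-value filter (default P < 1e-4) and greedy clumping at an r-squared
threshold (default 0.4).  Proteins whose cis region yields no surviving
variant return ``None`` ("no instrument") and are excluded downstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .sumstats_io import HarmonizedSet

logger = logging.getLogger("targetmr")


@dataclass(frozen=True)
class InstrumentSpec:
    """Selection parameters: exposure p-value cutoff and pairwise r2 cutoff."""

    p_threshold: float = 1e-4
    r2_threshold: float = 0.4

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ValueError(f"p_threshold must be in (0, 1), got {self.p_threshold}")
        if not (0 < self.r2_threshold <= 1):
            raise ValueError(f"r2_threshold must be in (0, 1], got {self.r2_threshold}")


@dataclass(frozen=True)
class Instrument:
    harmonized: HarmonizedSet
    spec: InstrumentSpec
    f_stat: float


def clump_greedy(hset: HarmonizedSet, r2_threshold: float) -> HarmonizedSet:
    """Greedy LD clumping at ``r2_threshold`` on squared signed correlation.

    Variants are visited in ascending exposure p-value (ties broken by
    genomic position, then variant ID, for cross-platform determinism); a
    variant is kept iff its r2 with every already-kept variant is at or
    below the threshold.  The output preserves genomic order.
    """
    m = len(hset)
    if m <= 1:
        return hset
    order = sorted(
        range(m), key=lambda i: (hset.p_X[i], hset.pos[i], hset.variant_ids[i])
    )
    r2 = hset.rho**2
    kept: list[int] = []
    for i in order:
        if all(r2[i, j] <= r2_threshold for j in kept):
            kept.append(i)
    kept.sort(key=lambda i: (hset.pos[i], hset.variant_ids[i]))
    return hset.subset(kept)


def f_statistic(hset: HarmonizedSet) -> float:
    """Mean per-variant F statistic, F_j = (b_X,j / se_X,j)^2.

    Values well above ~10-15 indicate low risk of weak-instrument bias.
    """
    if len(hset) == 0:
        raise ValueError("cannot compute F statistic on an empty set")
    return float(np.mean((hset.b_X / hset.se_X) ** 2))


def select_instruments(
    hset: HarmonizedSet, spec: InstrumentSpec = InstrumentSpec()
) -> Instrument | None:
    """Apply the p filter then greedy clumping; ``None`` means no instrument."""
    passing = np.flatnonzero(hset.p_X <= spec.p_threshold)
    if passing.size == 0:
        logger.info(
            "select_instruments: no variant at p<=%g, protein excluded",
            spec.p_threshold,
        )
        return None
    filtered = hset.subset(passing)
    clumped = clump_greedy(filtered, spec.r2_threshold)
    return Instrument(harmonized=clumped, spec=spec, f_stat=f_statistic(clumped))


def write_instrument(inst: Instrument, path_tsv: str | Path, path_json: str | Path) -> None:
    """Export the selected variants as TSV plus a JSON sidecar (spec and F)."""
    h = inst.harmonized
    pd.DataFrame(
        {
            "SNP": h.variant_ids,
            "POS": h.pos.astype(int),
            "BETA_X": h.b_X,
            "SE_X": h.se_X,
            "P_X": h.p_X,
            "N_X": h.n_X,
            "BETA_Y": h.b_Y,
            "SE_Y": h.se_Y,
            "N_Y": h.n_Y,
        }
    ).to_csv(path_tsv, sep="\t", index=False)
    Path(path_json).write_text(
        json.dumps({"spec": asdict(inst.spec), "f_stat": inst.f_stat,
                    "n_variants": len(h)}, indent=1)
    )
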
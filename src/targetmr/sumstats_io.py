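"""Summary-statistics and LD-matrix I/O, cis-region extraction, harmonization.

GWAS summary statistics are exchanged as tab-separated tables with a header
row.  The canonical column names are ``SNP CHR POS EA OA EAF BETA SE P N``;
a *dialect* mapping lets callers rename any of them.  Coordinates are 1-based
and all intervals are closed, matching the usual GWAS convention.

LD is exchanged as a plain whitespace-delimited square correlation matrix
plus a sidecar file with one variant ID per line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("targetmr")

CANONICAL_COLUMNS = ("SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N")

#: complementary bases, used to spot palindromic (A/T, C/G) variants
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SumstatsFormatError(ValueError):
    """File-level format problem (missing column, bad matrix shape, ...)."""


class RowValidationError(ValueError):
    """A data row violating a per-variant invariant; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


class HarmonizationError(ValueError):
    """Raised when exposure and outcome share no usable variants."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantAssoc:
    """One variant's marginal association with one trait.

    ``beta`` is per SD of a quantitative trait (e.g. plasma protein level) or
    log-odds for a binary outcome; ``se`` is on the same scale.  ``eaf`` may
    be ``None`` when the source does not report allele frequencies.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    p: float
    n: float
    eaf: float | None = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise RowValidationError(f"se must be > 0, got {self.se}")
        if not (0 < self.p <= 1):
            raise RowValidationError(f"p must be in (0, 1], got {self.p}")
        if self.effect_allele == self.other_allele:
            raise RowValidationError(
                f"effect and other allele are identical ({self.effect_allele})"
            )
        if self.pos < 1:
            raise RowValidationError(f"pos must be >= 1, got {self.pos}")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise RowValidationError(f"eaf must be in [0, 1], got {self.eaf}")

    @property
    def is_palindromic(self) -> bool:
        return _COMPLEMENT.get(self.effect_allele.upper()) == self.other_allele.upper()


@dataclass(frozen=True)
class LDMatrix:
    """Ordered variant IDs plus their pairwise correlation matrix (signed r)."""

    variant_ids: tuple[str, ...]
    r: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        m = len(self.variant_ids)
        if r.shape != (m, m):
            raise SumstatsFormatError(
                f"LD matrix shape {r.shape} does not match {m} variant ids"
            )
        if np.max(np.abs(r - r.T)) > 1e-10:
            raise SumstatsFormatError("LD matrix is not symmetric within 1e-10")
        if np.max(np.abs(np.diag(r) - 1.0)) > 1e-8:
            raise SumstatsFormatError("LD matrix diagonal is not 1 within 1e-8")
        if np.max(np.abs(r)) > 1 + 1e-8:
            raise SumstatsFormatError("LD matrix has entries outside [-1, 1]")
        if m and np.min(np.linalg.eigvalsh(r)) < -1e-8:
            raise SumstatsFormatError("LD matrix is not PSD within 1e-8")
        object.__setattr__(self, "r", r)

    def subset(self, ids: Sequence[str]) -> "LDMatrix":
        """Restrict (and reorder) the matrix to ``ids``."""
        index = {v: i for i, v in enumerate(self.variant_ids)}
        try:
            idx = [index[v] for v in ids]
        except KeyError as exc:
            raise KeyError(f"variant {exc.args[0]!r} not in LD matrix") from None
        return LDMatrix(tuple(ids), self.r[np.ix_(idx, idx)])


@dataclass(frozen=True)
class CisRegion:
    """Variants falling within ``window`` bp of a gene body (closed interval)."""

    gene_id: str
    anchor_start: int
    anchor_end: int
    window: int
    variants: tuple[VariantAssoc, ...]


@dataclass
class HarmonizedSet:
    """Allele-aligned exposure/outcome effects for a common set of variants.

    All vectors and the LD submatrix ``rho`` share order and length.  The
    exposure p-values and genomic positions are carried along because the
    instrument-selection step filters and tie-breaks on them.
    """

    variant_ids: tuple[str, ...]
    pos: np.ndarray
    b_X: np.ndarray
    se_X: np.ndarray
    p_X: np.ndarray
    n_X: np.ndarray
    b_Y: np.ndarray
    se_Y: np.ndarray
    n_Y: np.ndarray
    rho: np.ndarray

    def __post_init__(self) -> None:
        m = len(self.variant_ids)
        for name in ("pos", "b_X", "se_X", "p_X", "n_X", "b_Y", "se_Y", "n_Y"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (m,):
                raise ValueError(f"{name} has shape {arr.shape}, expected ({m},)")
            setattr(self, name, arr)
        rho = np.asarray(self.rho, dtype=float)
        if rho.shape != (m, m):
            raise ValueError(f"rho has shape {rho.shape}, expected ({m}, {m})")
        self.rho = rho
        if m and (np.any(self.se_X <= 0) or np.any(self.se_Y <= 0)):
            raise ValueError("all standard errors must be > 0")

    def __len__(self) -> int:
        return len(self.variant_ids)

    def subset(self, idx: Sequence[int]) -> "HarmonizedSet":
        idx = np.asarray(idx, dtype=int)
        return HarmonizedSet(
            variant_ids=tuple(self.variant_ids[i] for i in idx),
            pos=self.pos[idx],
            b_X=self.b_X[idx],
            se_X=self.se_X[idx],
            p_X=self.p_X[idx],
            n_X=self.n_X[idx],
            b_Y=self.b_Y[idx],
            se_Y=self.se_Y[idx],
            n_Y=self.n_Y[idx],
            rho=self.rho[np.ix_(idx, idx)],
        )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def _resolve_dialect(columns: Iterable[str], dialect: Mapping[str, str] | None) -> dict:
    """Map canonical column names to the file's actual names."""
    dialect = dict(dialect or {})
    mapping = {canon: dialect.get(canon, canon) for canon in CANONICAL_COLUMNS}
    present = set(columns)
    mandatory = [c for c in CANONICAL_COLUMNS if c != "EAF"]
    for canon in mandatory:
        if mapping[canon] not in present:
            raise SumstatsFormatError(
                f"mandatory column {mapping[canon]!r} (for {canon}) missing from header"
            )
    if mapping["EAF"] not in present:
        mapping["EAF"] = None
    return mapping


def read_sumstats(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> list[VariantAssoc]:
    """Read a tab-separated summary-statistics file into VariantAssoc records.

    Parsing is locale-independent (decimal point).  Rows violating the
    per-variant invariants raise :class:`RowValidationError` with the
    1-based data line number (header is line 1).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    mapping = _resolve_dialect(df.columns, dialect)
    records: list[VariantAssoc] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row))
        try:
            eaf_raw = row[mapping["EAF"]] if mapping["EAF"] else ""
            records.append(
                VariantAssoc(
                    variant_id=row[mapping["SNP"]],
                    chrom=str(row[mapping["CHR"]]),
                    pos=int(row[mapping["POS"]]),
                    effect_allele=row[mapping["EA"]],
                    other_allele=row[mapping["OA"]],
                    eaf=float(eaf_raw) if eaf_raw not in ("", "NA") else None,
                    beta=float(row[mapping["BETA"]]),
                    se=float(row[mapping["SE"]]),
                    p=float(row[mapping["P"]]),
                    n=float(row[mapping["N"]]),
                )
            )
        except RowValidationError as exc:
            raise RowValidationError(str(exc), line=i) from None
        except (TypeError, ValueError) as exc:
            raise RowValidationError(f"unparseable row: {exc}", line=i) from None
    return records


def write_sumstats(records: Sequence[VariantAssoc], path: str | Path) -> None:
    """Write records as a canonical-column TSV (missing EAF encoded as NA)."""
    df = pd.DataFrame(
        {
            "SNP": [v.variant_id for v in records],
            "CHR": [v.chrom for v in records],
            "POS": [v.pos for v in records],
            "EA": [v.effect_allele for v in records],
            "OA": [v.other_allele for v in records],
            "EAF": [v.eaf if v.eaf is not None else "NA" for v in records],
            "BETA": [repr(v.beta) for v in records],
            "SE": [repr(v.se) for v in records],
            "P": [repr(v.p) for v in records],
            "N": [repr(v.n) for v in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_ld_matrix(path_matrix: str | Path, path_ids: str | Path) -> LDMatrix:
    """Read a square LD matrix plus its one-ID-per-line sidecar.

    Asymmetries up to 1e-8 are symmetrized by averaging; anything larger is
    a format error (it is reported, not silently repaired).
    """
    r = np.loadtxt(path_matrix, dtype=float, ndmin=2)
    ids = [line.strip() for line in Path(path_ids).read_text().splitlines() if line.strip()]
    if r.shape[0] != r.shape[1]:
        raise SumstatsFormatError(f"LD matrix is not square: shape {r.shape}")
    if r.shape[0] != len(ids):
        raise SumstatsFormatError(
            f"LD matrix dimension {r.shape[0]} does not match {len(ids)} ids"
        )
    asym = np.max(np.abs(r - r.T)) if r.size else 0.0
    if asym > 1e-8:
        raise SumstatsFormatError(f"LD matrix asymmetry {asym:.3g} exceeds 1e-8")
    r = (r + r.T) / 2.0
    return LDMatrix(tuple(ids), r)


def write_ld_matrix(ld: LDMatrix, path_matrix: str | Path, path_ids: str | Path) -> None:
    np.savetxt(path_matrix, ld.r, fmt="%.17g")
    Path(path_ids).write_text("\n".join(ld.variant_ids) + "\n")


# ---------------------------------------------------------------------------
# cis-region extraction and harmonization
# ---------------------------------------------------------------------------


def extract_cis_region(
    variants: Iterable[VariantAssoc],
    gene_id: str,
    anchor_start: int,
    anchor_end: int,
    window: int = 200_000,
) -> CisRegion:
    """Keep variants within ``window`` bp of the gene body (closed interval).

    The default +/-200 kb window is the usual cis-pQTL definition.  Output is
    sorted by position (ties by ID) regardless of input order; an empty
    region is a valid result.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    lo, hi = anchor_start - window, anchor_end + window
    kept = sorted(
        (v for v in variants if lo <= v.pos <= hi),
        key=lambda v: (v.pos, v.variant_id),
    )
    return CisRegion(gene_id, anchor_start, anchor_end, window, tuple(kept))


def harmonize(
    exposure: Sequence[VariantAssoc],
    outcome: Sequence[VariantAssoc],
    rho: LDMatrix,
    drop_palindromic: bool = True,
) -> HarmonizedSet:
    """Align outcome effects onto the exposure's effect-allele frame.

    Variants are joined by ID.  When the outcome's effect/other alleles are
    swapped relative to the exposure, the outcome beta is negated (and eaf
    complemented); variants whose allele pairs do not match either way are
    dropped with a logged reason, as are palindromic (A/T, C/G) variants when
    ``drop_palindromic`` is set.  The LD matrix is restricted and reordered
    to the survivors.
    """
    out_by_id = {v.variant_id: v for v in outcome}
    ld_ids = set(rho.variant_ids)
    kept_exp: list[VariantAssoc] = []
    kept_out: list[VariantAssoc] = []
    for e in exposure:
        o = out_by_id.get(e.variant_id)
        if o is None:
            continue
        if e.variant_id not in ld_ids:
            logger.info("harmonize: %s dropped (absent from LD matrix)", e.variant_id)
            continue
        if drop_palindromic and e.is_palindromic:
            logger.info("harmonize: %s dropped (palindromic %s/%s)",
                        e.variant_id, e.effect_allele, e.other_allele)
            continue
        if (o.effect_allele, o.other_allele) == (e.effect_allele, e.other_allele):
            kept_out.append(o)
        elif (o.effect_allele, o.other_allele) == (e.other_allele, e.effect_allele):
            kept_out.append(
                replace(
                    o,
                    effect_allele=e.effect_allele,
                    other_allele=e.other_allele,
                    beta=-o.beta,
                    eaf=None if o.eaf is None else 1.0 - o.eaf,
                )
            )
        else:
            logger.info(
                "harmonize: %s dropped (allele mismatch %s/%s vs %s/%s)",
                e.variant_id, e.effect_allele, e.other_allele,
                o.effect_allele, o.other_allele,
            )
            continue
        kept_exp.append(e)
    if not kept_exp:
        raise HarmonizationError("no overlapping variants between exposure and outcome")
    ids = tuple(v.variant_id for v in kept_exp)
    return HarmonizedSet(
        variant_ids=ids,
        pos=np.array([v.pos for v in kept_exp], dtype=float),
        b_X=np.array([v.beta for v in kept_exp]),
        se_X=np.array([v.se for v in kept_exp]),
        p_X=np.array([v.p for v in kept_exp]),
        n_X=np.array([v.n for v in kept_exp]),
        b_Y=np.array([v.beta for v in kept_out]),
        se_Y=np.array([v.se for v in kept_out]),
        n_Y=np.array([v.n for v in kept_out]),
        rho=rho.subset(ids).r,
    )
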
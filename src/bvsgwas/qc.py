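"""SNP quality control and design-matrix coding.

Filtering removes monomorphic SNPs first, then SNPs below the minor
allele frequency threshold among the remainder, so the two reported
counts are disjoint.  Design coding produces additive allele-count
columns (optionally mean-centred) and, optionally, heterozygote-indicator
dominance columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GenotypeMatrix


@dataclass(frozen=True)
class QCReport:
    n_input: int
    n_monomorphic: int
    n_low_maf: int
    n_retained: int
    maf: np.ndarray            # per input SNP
    retained_idx: np.ndarray   # indices into the input matrix

    def __post_init__(self):
        assert self.n_monomorphic + self.n_low_maf + self.n_retained == self.n_input

    def to_frame(self) -> pd.DataFrame:
        status = np.full(self.n_input, "retained", dtype=object)
        status[self.maf == 0.0] = "monomorphic"
        keep = np.zeros(self.n_input, dtype=bool)
        keep[self.retained_idx] = True
        status[(self.maf > 0.0) & ~keep] = "low_maf"
        return pd.DataFrame({"maf": self.maf, "status": status})


def compute_maf(codes: np.ndarray) -> float:
    """Minor allele frequency min(p, 1-p) with p = mean(code)/2.

    Missing codes (negative) are excluded; all-missing raises.
    """
    codes = np.asarray(codes, dtype=float)
    ok = codes >= 0
    if not np.any(ok):
        raise ValueError("all genotypes missing at this SNP")
    p = codes[ok].mean() / 2.0
    return float(min(p, 1.0 - p))


def compute_maf_matrix(codes: np.ndarray) -> np.ndarray:
    """Vectorised per-column MAF over non-missing entries."""
    X = np.asarray(codes, dtype=float)
    X = np.where(X < 0, np.nan, X)
    if np.any(np.all(np.isnan(X), axis=0)):
        raise ValueError("a SNP column is entirely missing")
    p = np.nanmean(X, axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


def filter_snps(g: GenotypeMatrix, maf_threshold: float = 0.01
                ) -> tuple[GenotypeMatrix, QCReport]:
    """Drop monomorphic SNPs, then SNPs with MAF < threshold.

    SNP order and the genetic map are preserved for retained SNPs.
    """
    if not (0.0 <= maf_threshold < 0.5):
        raise ValueError("maf_threshold must lie in [0, 0.5)")
    maf = compute_maf_matrix(g.codes)
    mono = maf == 0.0
    low = (~mono) & (maf < maf_threshold)
    keep = np.flatnonzero(~mono & ~low)
    report = QCReport(
        n_input=g.n_snps,
        n_monomorphic=int(mono.sum()),
        n_low_maf=int(low.sum()),
        n_retained=keep.size,
        maf=maf,
        retained_idx=keep,
    )
    return g.subset_snps(keep), report


def code_design(g: GenotypeMatrix, coding: str = "additive",
                center: bool = True) -> np.ndarray:
    """Design columns for the SNP regression.

    "additive": allele count per SNP; "additive+dominance" appends a
    heterozygote indicator column per SNP.  Centring subtracts column
    means; fitted values are unchanged by centring except through the
    intercept.  Missing codes are mean-imputed (with a warning) to keep
    the sampler dense.
    """
    if coding not in ("additive", "additive+dominance"):
        raise ValueError(f"unknown coding {coding!r}")
    X = g.codes.astype(np.float64)
    if np.any(X < 0):
        warnings.warn("missing genotypes mean-imputed per SNP", stacklevel=2)
        X = np.where(X < 0, np.nan, X)
        X = np.where(np.isnan(X), np.nanmean(X, axis=0, keepdims=True), X)
    cols = [X]
    if coding == "additive+dominance":
        cols.append((g.codes == 1).astype(np.float64))
    D = np.hstack(cols)
    if center:
        D = D - D.mean(axis=0, keepdims=True)
    return D
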
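"""Pedigree relationship machinery.

The additive (numerator) relationship matrix A holds expected additive
genetic relationships implied by the pedigree; the polygenic effects in
the association model are a ~ N(0, A * sigma_a^2).  A is built by the
tabular method with inbreeding; its sparse inverse comes from Henderson's
rules with Mendelian-sampling variances computed Meuwissen-Luo style from
parental inbreeding coefficients.  A VanRaden genomic relationship matrix
is provided for the one-population kinship sanity check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data import GenotypeMatrix

UNKNOWN = -1


@dataclass
class Pedigree:
    """Ordered pedigree records (individual, sire, dam).

    Internally individuals are dense integer indices 0..n-1 in an order
    where parents precede offspring; ``UNKNOWN`` (-1) marks a missing
    parent.  External string ids are kept in ``ids`` and mapped at I/O.
    """

    sire: np.ndarray  # (n,) int, index of sire or UNKNOWN
    dam: np.ndarray   # (n,) int, index of dam or UNKNOWN
    ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        n = self.sire.size
        if self.dam.size != n:
            raise ValueError("sire and dam arrays must have equal length")
        for name, arr in (("sire", self.sire), ("dam", self.dam)):
            bad = (arr >= np.arange(n)) & (arr != UNKNOWN)
            if np.any(bad):
                i = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"{name} of individual {i} does not precede it "
                    "(pedigree must be topologically ordered; cycles are invalid)"
                )
            if np.any(arr < UNKNOWN):
                raise ValueError(f"invalid {name} index")
        if not self.ids:
            self.ids = [f"I{k + 1:05d}" for k in range(n)]
        if len(self.ids) != n:
            raise ValueError("ids length mismatch")

    @property
    def n(self) -> int:
        return self.sire.size

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    def to_frame(self) -> pd.DataFrame:
        def name(k):
            return "0" if k == UNKNOWN else self.ids[k]
        return pd.DataFrame({
            "id": self.ids,
            "sire": [name(s) for s in self.sire],
            "dam": [name(d) for d in self.dam],
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        """Build from an (id, sire, dam) frame; "0"/NA = unknown parent.

        Records may arrive in any order as long as no individual is its own
        ancestor; they are sorted topologically (parents first).
        """
        ids = [str(x) for x in df.iloc[:, 0]]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual id in pedigree")
        sires = [str(x) for x in df.iloc[:, 1]]
        dams = [str(x) for x in df.iloc[:, 2]]
        known = set(ids)
        missing = {"0", "", "NA", "nan", "None"}
        for p in sires + dams:
            if p not in known and p not in missing:
                raise ValueError(f"parent {p!r} has no pedigree record")
        # Kahn-style topological sort, stable in input order
        order: list[int] = []
        placed: set[str] = set()
        remaining = list(range(len(ids)))
        while remaining:
            progress = []
            for k in remaining:
                s, d = sires[k], dams[k]
                if (s in missing or s in placed) and (d in missing or d in placed):
                    progress.append(k)
            if not progress:
                raise ValueError("pedigree contains a cycle")
            for k in progress:
                order.append(k)
                placed.add(ids[k])
            remaining = [k for k in remaining if k not in progress]
        index = {ids[k]: i for i, k in enumerate(order)}
        sire = np.array([index.get(sires[k], UNKNOWN) for k in order], dtype=np.int64)
        dam = np.array([index.get(dams[k], UNKNOWN) for k in order], dtype=np.int64)
        return cls(sire, dam, [ids[k] for k in order])


def build_A(ped: Pedigree) -> np.ndarray:
    """Numerator relationship matrix by the tabular method, with inbreeding.

    A[j, i] = (A[s(j), i] + A[d(j), i]) / 2 for i < j and
    A[j, j] = 1 + A[s(j), d(j)] / 2; unknown parents contribute 0.
    """
    n = ped.n
    A = np.zeros((n, n))
    for j in range(n):
        s, d = ped.sire[j], ped.dam[j]
        row = np.zeros(j)
        if s != UNKNOWN:
            row += 0.5 * A[s, :j]
        if d != UNKNOWN:
            row += 0.5 * A[d, :j]
        A[j, :j] = row
        A[:j, j] = row
        A[j, j] = 1.0 + (0.5 * A[s, d] if (s != UNKNOWN and d != UNKNOWN) else 0.0)
    return A


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F_i = A_ii - 1 (tabular method)."""
    return np.diag(build_A(ped)) - 1.0


def build_A_inverse(ped: Pedigree) -> sp.csr_matrix:
    """Sparse inverse of A via Henderson's rules with inbreeding.

    The Mendelian-sampling variance of individual i with parents s, d is
    d_i = 0.5 - 0.25 (F_s + F_d), with 0.75 - 0.25 F for one known parent
    and 1 for founders.  Each individual contributes the usual
    {1, -1/2, 1/4}-patterned block scaled by 1/d_i.
    """
    n = ped.n
    F = inbreeding(ped)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s != UNKNOWN and d != UNKNOWN:
            di = 0.5 - 0.25 * (F[s] + F[d])
        elif s != UNKNOWN or d != UNKNOWN:
            p = s if s != UNKNOWN else d
            di = 0.75 - 0.25 * F[p]
        else:
            di = 1.0
        w = 1.0 / di
        add(i, i, w)
        for p in (s, d):
            if p != UNKNOWN:
                add(i, p, -0.5 * w)
                add(p, i, -0.5 * w)
                add(p, p, 0.25 * w)
        if s != UNKNOWN and d != UNKNOWN:
            add(s, d, 0.25 * w)
            add(d, s, 0.25 * w)
    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    Ainv.sum_duplicates()
    return Ainv


def genomic_kinship(genotypes: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """VanRaden genomic relationship matrix Z Z' / (2 sum p(1-p)).

    Z holds allele counts centred by twice the observed allele frequency;
    monomorphic SNPs carry no information and are dropped.  Used here for
    the one-population sanity check (e.g. comparing mean kinship within
    and between sire and dam groups).
    """
    codes = genotypes.codes if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes)
    if codes.shape[0] < 2:
        raise ValueError("need at least two individuals")
    X = codes.astype(float)
    X[X < 0] = np.nan
    p = np.nanmean(X, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not np.any(poly):
        raise ValueError("all SNPs are monomorphic")
    X = X[:, poly]
    p = p[poly]
    Z = np.where(np.isnan(X), 0.0, X - 2.0 * p)
    denom = 2.0 * np.sum(p * (1.0 - p))
    return Z @ Z.T / denom
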
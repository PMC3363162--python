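"""Core in-memory containers: genetic map and genotype matrix.

Genotypes are minor-allele-count codes 0/1/2 (int8; -1 = missing) for
``n`` individuals at ``m`` SNPs, carried together with a genetic map
(chromosome, position in Morgan) and individual / SNP identifiers.
Phase, when known (e.g. from the gene-drop simulator), is kept as two
haplotype matrices so that parent-of-origin effects can be modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1


@dataclass(frozen=True)
class GeneticMap:
    """Per-SNP chromosome index (1-based) and position in Morgan.

    Positions must be strictly increasing within a chromosome.
    """

    chrom: np.ndarray  # (m,) int, 1-based
    pos: np.ndarray    # (m,) float, Morgan

    def __post_init__(self):
        chrom = np.asarray(self.chrom, dtype=np.int64)
        pos = np.asarray(self.pos, dtype=np.float64)
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "pos", pos)
        if chrom.shape != pos.shape or chrom.ndim != 1:
            raise ValueError("chrom and pos must be 1-D arrays of equal length")
        if np.any(pos < 0):
            raise ValueError("map positions must be >= 0 Morgan")
        for c in np.unique(chrom):
            p = pos[chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")

    @property
    def n_snps(self) -> int:
        return self.chrom.size

    @property
    def chromosomes(self) -> np.ndarray:
        return np.unique(self.chrom)

    def chrom_slice(self, c: int) -> np.ndarray:
        """Indices of the SNPs on chromosome ``c``."""
        return np.flatnonzero(self.chrom == c)

    @classmethod
    def equally_spaced(cls, n_chrom: int = 5, snps_per_chrom: int = 1998,
                       chrom_length: float = 1.0) -> "GeneticMap":
        """Equally spaced SNPs on ``n_chrom`` chromosomes of ``chrom_length`` Morgan.

        SNPs sit at interval midpoints so positions stay inside (0, L).
        """
        if n_chrom < 1 or snps_per_chrom < 1:
            raise ValueError("need at least one chromosome and one SNP")
        step = chrom_length / snps_per_chrom
        within = (np.arange(snps_per_chrom) + 0.5) * step
        chrom = np.repeat(np.arange(1, n_chrom + 1), snps_per_chrom)
        pos = np.tile(within, n_chrom)
        return cls(chrom, pos)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom, "pos_morgan": self.pos})

    def subset(self, idx: np.ndarray) -> "GeneticMap":
        return GeneticMap(self.chrom[idx], self.pos[idx])


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs allele-count codes with an attached genetic map.

    Parameters
    ----------
    codes
        (n, m) int8 array with entries in {0, 1, 2} or ``MISSING`` (-1).
    gmap
        Genetic map for the m SNP columns.
    ids
        Individual identifiers (strings); defaults to "I0001", ...
    snp_ids
        SNP identifiers; default "snp<chrom>_<k>".
    paternal, maternal
        Optional phased haplotypes, (n, m) uint8 each; ``codes`` must equal
        their sum when present.
    """

    codes: np.ndarray
    gmap: GeneticMap
    ids: list[str] = field(default_factory=list)
    snp_ids: list[str] = field(default_factory=list)
    paternal: np.ndarray | None = None
    maternal: np.ndarray | None = None

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D (individuals x SNPs) array")
        n, m = self.codes.shape
        if m != self.gmap.n_snps:
            raise ValueError(f"map has {self.gmap.n_snps} SNPs, matrix has {m} columns")
        bad = (self.codes < -1) | (self.codes > 2)
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise ValueError(f"invalid genotype code {self.codes[i, j]} at row {i}, column {j}")
        if not self.ids:
            self.ids = [f"I{k + 1:05d}" for k in range(n)]
        if len(self.ids) != n:
            raise ValueError("ids length does not match number of individuals")
        if not self.snp_ids:
            self.snp_ids = [f"snp{c}_{k + 1}" for k, c in enumerate(self.gmap.chrom)]
        if len(self.snp_ids) != m:
            raise ValueError("snp_ids length does not match number of SNPs")
        if (self.paternal is None) != (self.maternal is None):
            raise ValueError("provide both or neither of paternal/maternal haplotypes")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    @property
    def phased(self) -> bool:
        return self.paternal is not None

    def subset_snps(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            codes=self.codes[:, idx],
            gmap=self.gmap.subset(idx),
            ids=list(self.ids),
            snp_ids=[self.snp_ids[k] for k in idx],
            paternal=None if self.paternal is None else self.paternal[:, idx],
            maternal=None if self.maternal is None else self.maternal[:, idx],
        )

    def subset_individuals(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            codes=self.codes[idx],
            gmap=self.gmap,
            ids=[self.ids[k] for k in idx],
            snp_ids=list(self.snp_ids),
            paternal=None if self.paternal is None else self.paternal[idx],
            maternal=None if self.maternal is None else self.maternal[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.codes, index=self.ids, columns=self.snp_ids)
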
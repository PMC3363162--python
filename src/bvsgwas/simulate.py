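"""Forward population simulator for a half-sib/full-sib breeding design.

Emulates the statistical structure of a classic simulated QTL-mapping
workshop dataset: an outbred base population with linkage disequilibrium
built up by many generations of random mating in a small population, a
three-generation breeding pyramid (sires x dams x full-sib offspring),
dense equally spaced SNPs on 5 chromosomes of 1 Morgan, and a normally
distributed trait controlled by a handful of QTL (additive, a linked
pair in repulsion, an imprinted locus and an epistatic pair) plus a
pedigree polygenic term, at a configurable heritability.  Only a subset
of each full-sib family is phenotyped and parents are never phenotyped.

The simulator is fully deterministic given its master seed: all stages
draw child seeds from one ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._meiosis import (drop_haplotypes, map_arrays, random_mating,
                       sample_crossover_counts)
from .data import GeneticMap, GenotypeMatrix
from .pedigree import UNKNOWN, Pedigree

__all__ = [
    "FounderHaplotypes", "QTL", "QTLArchitecture", "TrueValues",
    "PopSimConfig", "SimulatedPopulation", "QTLSpecEntry",
    "simulate_founder_haplotypes", "build_pedigree", "drop_genotypes",
    "assign_qtl_architecture", "simulate_phenotypes", "simulate_population",
    "DEFAULT_QTL_SPEC",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic 31-bit child seeds for the simulation stages."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31 - 1)) + 1 for s in state]


@dataclass(frozen=True)
class FounderHaplotypes:
    """2*n_founders binary haplotypes over the mapped SNPs."""

    haps: np.ndarray  # (2*n_founders, m) uint8

    @property
    def n_founders(self) -> int:
        return self.haps.shape[0] // 2

    @property
    def freq(self) -> np.ndarray:
        return self.haps.mean(axis=0)


@dataclass(frozen=True)
class QTL:
    """One causal entry: a SNP (or SNP pair) with its mode and effect.

    modes: "additive" (effect per allele copy), "imprinted" (effect
    carried by one parental allele only), "epistatic" (product term on
    centred codes of two loci, one shared effect).
    """

    snp_idx: tuple[int, ...]
    mode: str
    effect: float
    parent_of_origin: str = "paternal"  # imprinted mode only

    def __post_init__(self):
        if self.mode not in ("additive", "imprinted", "epistatic"):
            raise ValueError(f"unknown QTL mode {self.mode!r}")
        n = len(self.snp_idx)
        if self.mode == "epistatic":
            if n != 2 or self.snp_idx[0] == self.snp_idx[1]:
                raise ValueError("an epistatic pair needs two distinct SNPs")
        elif n != 1:
            raise ValueError(f"{self.mode} QTL references exactly one SNP")


@dataclass(frozen=True)
class QTLArchitecture:
    qtls: tuple[QTL, ...]

    @property
    def causal_snps(self) -> np.ndarray:
        """Sorted unique indices of all SNPs involved in any QTL."""
        idx = [k for q in self.qtls for k in q.snp_idx]
        return np.unique(np.asarray(idx, dtype=np.int64)) if idx else np.empty(0, dtype=np.int64)

    def __len__(self):
        return len(self.qtls)


@dataclass(frozen=True)
class QTLSpecEntry:
    """Requested QTL: chromosome, target position (Morgan), mode, raw weight.

    Weights are relative; :func:`simulate_phenotypes` rescales all effects
    jointly so the QTL explain the configured share of genetic variance.
    """

    chrom: int
    pos: float
    mode: str = "additive"
    weight: float = 1.0
    pos2: float | None = None  # second locus of an epistatic pair


# One additive QTL on chr 1, two on chr 2, a linked pair in repulsion on
# chr 3, an imprinted QTL on chr 4, and an epistatic pair on chr 5: seven
# entries spanning all five chromosomes.
DEFAULT_QTL_SPEC: tuple[QTLSpecEntry, ...] = (
    QTLSpecEntry(1, 0.50, "additive", 1.4),
    QTLSpecEntry(2, 0.30, "additive", 1.0),
    QTLSpecEntry(2, 0.70, "additive", 0.8),
    QTLSpecEntry(3, 0.48, "additive", 0.9),
    QTLSpecEntry(3, 0.52, "additive", -0.9),   # repulsion partner
    QTLSpecEntry(4, 0.50, "imprinted", 0.9),
    QTLSpecEntry(5, 0.30, "epistatic", 1.1, pos2=0.70),
)


@dataclass
class TrueValues:
    """Per-individual simulated truth.

    ``bv`` is the additive breeding value (polygenic effect plus the
    least-squares additive projection of the QTL genotypic value onto
    allele counts); ``genetic_value`` additionally carries imprinting and
    epistatic deviations; ``phenotype`` is NaN for unphenotyped
    individuals (all parents, and the unsampled offspring).
    """

    ids: list[str]
    bv: np.ndarray
    genetic_value: np.ndarray
    phenotype: np.ndarray
    residual_var: float
    h2_target: float

    @property
    def phenotyped(self) -> np.ndarray:
        return ~np.isnan(self.phenotype)

    def realized_h2(self) -> float:
        """Var(genetic) / Var(phenotype) among phenotyped individuals."""
        ok = self.phenotyped
        return float(np.var(self.genetic_value[ok]) / np.var(self.phenotype[ok]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.ids,
            "true_bv": self.bv,
            "genetic_value": self.genetic_value,
            "phenotype": self.phenotype,
        })


def simulate_founder_haplotypes(n_founders: int, gmap: GeneticMap, *,
                                init_freq: tuple[float, float] = (0.05, 0.95),
                                n_burn_generations: int = 200,
                                burn_pop_size: int = 150,
                                chrom_lengths=None,
                                seed: int = 0) -> FounderHaplotypes:
    """Founder haplotypes with drift-and-recombination LD.

    A population of ``burn_pop_size`` diploids starts at linkage
    equilibrium with per-locus allele frequencies drawn uniformly from
    ``init_freq`` and random-mates for ``n_burn_generations`` (building
    LD that decays with map distance, and letting drift push some loci to
    rare or monomorphic frequencies); the final generation is expanded to
    ``n_founders`` individuals.  ``n_burn_generations=0`` returns
    independent Bernoulli haplotypes (linkage equilibrium).
    """
    if gmap.n_snps == 0:
        raise ValueError("map has no SNPs")
    if n_founders < 2:
        raise ValueError("need at least two founders")
    if n_burn_generations < 0:
        raise ValueError("n_burn_generations must be >= 0")
    s_init, s_burn = _child_seeds(seed, 2)
    rng = np.random.default_rng(s_init)
    m = gmap.n_snps
    p = rng.uniform(init_freq[0], init_freq[1], size=m)
    if n_burn_generations == 0:
        haps = (rng.random((2 * n_founders, m)) < p).astype(np.uint8)
        return FounderHaplotypes(haps)
    base = (rng.random((burn_pop_size, 2, m)) < p).astype(np.uint8)
    offsets, pos, lens = map_arrays(gmap.chrom, gmap.pos, chrom_lengths)
    out = random_mating(base, n_burn_generations, n_founders, offsets, pos, lens, s_burn)
    return FounderHaplotypes(out.reshape(2 * n_founders, m))


def build_pedigree(n_sires: int, n_dams_per_sire: int,
                   n_offspring_per_dam: int) -> Pedigree:
    """Breeding-pyramid pedigree: founder sires and dams, full-sib families.

    Each sire is mated to its own ``n_dams_per_sire`` dams and every mating
    produces ``n_offspring_per_dam`` full sibs, giving
    ``n_sires * (1 + n_dams_per_sire * (1 + n_offspring_per_dam))``
    individuals in total, founders first.
    """
    if min(n_sires, n_dams_per_sire, n_offspring_per_dam) < 1:
        raise ValueError("all design counts must be >= 1")
    n_dams = n_sires * n_dams_per_sire
    sire_ids = [f"S{k + 1:04d}" for k in range(n_sires)]
    dam_ids = [f"D{k + 1:04d}" for k in range(n_dams)]
    sire = [UNKNOWN] * (n_sires + n_dams)
    dam = [UNKNOWN] * (n_sires + n_dams)
    ids = sire_ids + dam_ids
    o = 0
    for s in range(n_sires):
        for dd in range(n_dams_per_sire):
            d = n_sires + s * n_dams_per_sire + dd
            for _ in range(n_offspring_per_dam):
                o += 1
                ids.append(f"O{o:05d}")
                sire.append(s)
                dam.append(d)
    return Pedigree(np.array(sire), np.array(dam), ids)


def drop_genotypes(ped: Pedigree, founders: FounderHaplotypes, gmap: GeneticMap,
                   *, chrom_lengths=None, seed: int = 0) -> GenotypeMatrix:
    """Gene-drop founder haplotypes through the pedigree (phased output)."""
    n_found = int(ped.is_founder.sum())
    if founders.n_founders != n_found:
        raise ValueError(
            f"pedigree has {n_found} founders but {founders.n_founders} "
            "founder haplotype pairs were supplied")
    half = (ped.sire == UNKNOWN) ^ (ped.dam == UNKNOWN)
    if np.any(half):
        raise ValueError("gene drop requires both parents known for every non-founder")
    offsets, pos, lens = map_arrays(gmap.chrom, gmap.pos, chrom_lengths)
    (s,) = _child_seeds(seed, 1)
    haps, _ = drop_haplotypes(ped.sire, ped.dam, founders.haps, offsets, pos, lens, s)
    pat = haps[:, 0, :]
    mat = haps[:, 1, :]
    return GenotypeMatrix(
        codes=(pat + mat).astype(np.int8), gmap=gmap, ids=list(ped.ids),
        paternal=pat, maternal=mat,
    )


def count_crossovers(parent_haps: np.ndarray, gmap: GeneticMap, n_meioses: int,
                     *, chrom_lengths=None, seed: int = 0) -> np.ndarray:
    """Crossover count per simulated meiosis (diagnostic for the Haldane model)."""
    offsets, pos, lens = map_arrays(gmap.chrom, gmap.pos, chrom_lengths)
    return sample_crossover_counts(np.ascontiguousarray(parent_haps[0]),
                                   np.ascontiguousarray(parent_haps[1]),
                                   offsets, pos, lens, n_meioses, seed)


def assign_qtl_architecture(gmap: GeneticMap,
                            spec=DEFAULT_QTL_SPEC,
                            *, freqs: np.ndarray | None = None,
                            min_qtl_maf: float = 0.15,
                            seed: int = 0) -> QTLArchitecture:
    """Place the requested QTL at mapped SNPs.

    Each entry is placed at the unused SNP nearest its target position on
    its chromosome, restricted (when allele frequencies are supplied) to
    SNPs with MAF >= ``min_qtl_maf`` so causal loci are well segregating.
    Raises if the requested positions collide, i.e. a chromosome has no
    eligible SNP left for an entry.
    """
    del seed  # placement is deterministic; kept for interface symmetry
    qtls: list[QTL] = []
    used: set[int] = set()

    def nearest(chrom: int, pos: float) -> int:
        idx = gmap.chrom_slice(chrom)
        if idx.size == 0:
            raise ValueError(f"no SNPs on chromosome {chrom}")
        if freqs is not None:
            maf = np.minimum(freqs[idx], 1.0 - freqs[idx])
            ok = idx[maf >= min_qtl_maf]
            if ok.size:
                idx = ok
        idx = np.array([k for k in idx if k not in used])
        if idx.size == 0:
            raise ValueError(f"QTL positions collide: no free SNP on chromosome {chrom}")
        k = int(idx[np.argmin(np.abs(gmap.pos[idx] - pos))])
        used.add(k)
        return k

    for e in spec:
        if e.mode == "epistatic":
            k1 = nearest(e.chrom, e.pos)
            k2 = nearest(e.chrom, e.pos2 if e.pos2 is not None else e.pos + 0.3)
            qtls.append(QTL((k1, k2), "epistatic", e.weight))
        else:
            qtls.append(QTL((nearest(e.chrom, e.pos),), e.mode, e.weight))
    return QTLArchitecture(tuple(qtls))


def _qtl_values(genotypes: GenotypeMatrix, architecture: QTLArchitecture) -> np.ndarray:
    """Raw (unscaled) QTL genotypic value per individual."""
    n = genotypes.n_individuals
    u = np.zeros(n)
    g = genotypes.codes.astype(float)
    for q in architecture.qtls:
        if q.mode == "additive":
            u += q.effect * g[:, q.snp_idx[0]]
        elif q.mode == "imprinted":
            if not genotypes.phased:
                raise ValueError("imprinted QTL require phased genotypes")
            hap = genotypes.paternal if q.parent_of_origin == "paternal" else genotypes.maternal
            u += q.effect * hap[:, q.snp_idx[0]].astype(float)
        else:  # epistatic: additive-by-additive product on centred codes
            a, b = q.snp_idx
            u += q.effect * (g[:, a] - 1.0) * (g[:, b] - 1.0)
    return u


def _additive_projection(genotypes: GenotypeMatrix, architecture: QTLArchitecture,
                         u: np.ndarray) -> np.ndarray:
    """Least-squares projection of the QTL value onto causal allele counts.

    This is the classical definition of the additive (breeding-value)
    component: average allele-substitution effects fitted in the realized
    population.
    """
    snps = architecture.causal_snps
    if snps.size == 0:
        return np.zeros_like(u)
    X = genotypes.codes[:, snps].astype(float)
    X = X - X.mean(axis=0)
    beta, *_ = np.linalg.lstsq(X, u - u.mean(), rcond=None)
    return X @ beta


def simulate_phenotypes(genotypes: GenotypeMatrix, architecture: QTLArchitecture,
                        ped: Pedigree, *, h2: float = 0.30,
                        polygenic_share: float = 0.30,
                        phenotyped_per_family: int = 10,
                        seed: int = 0) -> TrueValues:
    """Simulate a quantitative trait over the pedigree.

    Genetic value = scaled QTL genotypic value + pedigree polygenic effect
    (founders ~ N(0, s2); offspring = parent average + Mendelian sampling
    ~ N(0, s2/2)).  The two parts are rescaled so QTL explain
    ``1 - polygenic_share`` of the realized genetic variance, and the
    residual variance is set from the realized genetic variance so that
    Var(genetic)/Var(phenotype) matches ``h2``.  Parents are never
    phenotyped; within each full-sib family exactly
    ``phenotyped_per_family`` offspring receive a phenotype.
    """
    if not (0.0 < h2 < 1.0):
        raise ValueError("h2 must lie in (0, 1)")
    if not (0.0 <= polygenic_share <= 1.0):
        raise ValueError("polygenic_share must lie in [0, 1]")
    n = ped.n
    if genotypes.n_individuals != n:
        raise ValueError("genotypes and pedigree cover different individuals")
    s_poly, s_env, s_fam = _child_seeds(seed, 3)

    # polygenic effects down the pedigree (unit founder variance)
    rng = np.random.default_rng(s_poly)
    a = np.zeros(n)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s == UNKNOWN and d == UNKNOWN:
            a[i] = rng.normal(0.0, 1.0)
        else:
            pa = (a[s] if s != UNKNOWN else 0.0) + (a[d] if d != UNKNOWN else 0.0)
            a[i] = pa / 2.0 + rng.normal(0.0, np.sqrt(0.5))

    u = _qtl_values(genotypes, architecture)
    qtl_share = 1.0 - polygenic_share if len(architecture) else 0.0
    var_u = np.var(u)
    if var_u == 0.0 and polygenic_share == 0.0:
        raise ValueError("degenerate genetics: no QTL variance and no polygenic share")
    c_q = np.sqrt(qtl_share / var_u) if var_u > 0 else 0.0
    c_p = np.sqrt(max(1.0 - qtl_share, 0.0) / np.var(a))
    u = c_q * (u - u.mean())
    a = c_p * a
    genetic = a + u
    bv = a + _additive_projection(genotypes, architecture, u)

    offspring = ~ped.is_founder
    var_g = np.var(genetic[offspring]) if offspring.any() else np.var(genetic)
    sigma_e2 = var_g * (1.0 - h2) / h2 if var_g > 0 else 1.0
    rng_env = np.random.default_rng(s_env)
    y = genetic + rng_env.normal(0.0, np.sqrt(sigma_e2), size=n)

    # phenotype mask: parents never phenotyped; sample within families
    rng_fam = np.random.default_rng(s_fam)
    mask = np.zeros(n, dtype=bool)
    fams: dict[tuple[int, int], list[int]] = {}
    for i in np.flatnonzero(offspring):
        fams.setdefault((int(ped.sire[i]), int(ped.dam[i])), []).append(i)
    for members in fams.values():
        k = min(phenotyped_per_family, len(members))
        chosen = rng_fam.choice(members, size=k, replace=False)
        mask[chosen] = True
    y = np.where(mask, y, np.nan)
    return TrueValues(list(ped.ids), bv, genetic, y, float(sigma_e2), h2)


@dataclass(frozen=True)
class PopSimConfig:
    """Complete configuration of one simulated dataset.

    The full-scale defaults mirror the emulated workshop design: a
    20-sire x 10-dams x 15-offspring pyramid (3,220 individuals), 9,990
    equally spaced SNPs on 5 chromosomes of 1 Morgan, 10 of 15 offspring
    per family phenotyped and trait heritability 0.30.  The burn-in
    approximates the stated recent history (random mating in a population
    of 150) with enough generations to build map-distance-dependent LD.
    """

    n_sires: int = 20
    n_dams_per_sire: int = 10
    n_offspring_per_dam: int = 15
    phenotyped_per_family: int = 10
    n_chrom: int = 5
    snps_per_chrom: int = 1998
    chrom_length: float = 1.0
    burn_generations: int = 200
    burn_pop_size: int = 150
    init_freq: tuple[float, float] = (0.05, 0.95)
    h2: float = 0.30
    polygenic_share: float = 0.30
    qtl_spec: tuple[QTLSpecEntry, ...] = DEFAULT_QTL_SPEC
    min_qtl_maf: float = 0.15

    @property
    def n_founders(self) -> int:
        return self.n_sires * (1 + self.n_dams_per_sire)

    def desk(self) -> "PopSimConfig":
        """Reduced preset for interactive work and tests.

        20 sires x 5 dams x 6 offspring (720 individuals, 600 offspring),
        350 SNPs per chromosome (roughly 1,000 survive QC after drift),
        4 of 6 offspring phenotyped per family and a shorter burn-in in a
        population of 100.
        """
        return replace(self, n_dams_per_sire=5, n_offspring_per_dam=6,
                       phenotyped_per_family=4, snps_per_chrom=350,
                       burn_generations=120, burn_pop_size=100)


@dataclass
class SimulatedPopulation:
    config: PopSimConfig
    seed: int
    gmap: GeneticMap
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    architecture: QTLArchitecture
    truth: TrueValues

    @property
    def phenotypes(self) -> pd.Series:
        return pd.Series(self.truth.phenotype, index=self.truth.ids, name="phenotype")


def simulate_population(config: PopSimConfig | None = None, *, seed: int = 0,
                        desk: bool = False) -> SimulatedPopulation:
    """Run the whole generator: founders -> pedigree -> gene drop -> trait."""
    cfg = config if config is not None else PopSimConfig()
    if desk:
        cfg = cfg.desk()
    gmap = GeneticMap.equally_spaced(cfg.n_chrom, cfg.snps_per_chrom, cfg.chrom_length)
    lens = [cfg.chrom_length] * cfg.n_chrom
    s_found, s_drop, s_phen = _child_seeds(seed + 101, 3)
    ped = build_pedigree(cfg.n_sires, cfg.n_dams_per_sire, cfg.n_offspring_per_dam)
    founders = simulate_founder_haplotypes(
        cfg.n_founders, gmap, init_freq=cfg.init_freq,
        n_burn_generations=cfg.burn_generations, burn_pop_size=cfg.burn_pop_size,
        chrom_lengths=lens, seed=s_found)
    geno = drop_genotypes(ped, founders, gmap, chrom_lengths=lens, seed=s_drop)
    arch = assign_qtl_architecture(gmap, cfg.qtl_spec, freqs=founders.freq,
                                   min_qtl_maf=cfg.min_qtl_maf)
    truth = simulate_phenotypes(
        geno, arch, ped, h2=cfg.h2, polygenic_share=cfg.polygenic_share,
        phenotyped_per_family=cfg.phenotyped_per_family, seed=s_phen)
    return SimulatedPopulation(cfg, seed, gmap, ped, geno, arch, truth)
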
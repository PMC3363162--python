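"""The Bayesian variable selection model (statsmodels-style Model object).

The observation model for the phenotyped individuals is

    y = mu + Z a + sum_k X_k alpha_k + e,

with a pedigree polygenic term a ~ N(0, A sigma_a^2) (A the numerator
relationship matrix), per-SNP allele-substitution effects alpha_k under a
two-component normal mixture prior

    alpha_k ~ N(0, sigma_g0^2) w.p. pi0,   N(0, sigma_g1^2) w.p. pi1,

a Beta(100, 1)-type prior on pi0 (prior mean pi1 = 1/101), bounded
uniform priors on all variances, and residuals e ~ N(0, I sigma_e^2).
The ratio sigma_g1^2 / sigma_g0^2 is held fixed (default 1:100) while
the common scale is estimated by a tuned Metropolis-Hastings scaling
move; everything else is Gibbs, with SNP effects and their mixture
indicators updated jointly in random disjoint pairs.

``BayesianVariableSelection(...).fit(...)`` returns a
:class:`~bvsgwas.results.BVSResults`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._chain import run_chain_kernel
from .data import GenotypeMatrix
from .pedigree import Pedigree, build_A_inverse
from .qc import code_design

__all__ = ["Priors", "MCMCConfig", "BayesianVariableSelection", "sample_pi"]


@dataclass(frozen=True)
class Priors:
    """Hyper-parameters of the mixture-prior model.

    ``sigma2_g0`` and ``sigma2_g1 = variance_ratio * sigma2_g0`` are the
    initial mixture-component variances (trait-variance units); their
    common scale is estimated while the ratio stays fixed.  The mixture
    proportion prior is Beta(``beta_b``, ``beta_a``) on pi0, i.e.
    Beta(``beta_a``, ``beta_b``) on pi1, default Beta(1, 100) with prior
    mean pi1 = 1/101.  Variance priors are uniform on ``var_bounds``
    (default lower 1e-8, upper 10 * Var(y), resolved at fit time).
    """

    pi0: float = 0.98
    sigma2_g0: float = 0.001
    variance_ratio: float = 100.0
    beta_a: float = 1.0
    beta_b: float = 100.0
    var_bounds: tuple[float, float] | None = None
    sigma2_a_init: float | None = None
    sigma2_e_init: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.pi0 <= 1.0):
            raise ValueError("pi0 must lie in [0, 1]")
        if self.variance_ratio <= 1.0:
            raise ValueError("variance_ratio must exceed 1")
        if self.sigma2_g0 <= 0.0:
            raise ValueError("sigma2_g0 must be positive")

    @property
    def pi1(self) -> float:
        return 1.0 - self.pi0

    @property
    def pi1_prior_mean(self) -> float:
        return self.beta_a / (self.beta_a + self.beta_b)


@dataclass(frozen=True)
class MCMCConfig:
    """Chain settings (defaults: 52,000 cycles, 2,000 burn-in, thin 10)."""

    n_cycles: int = 52_000
    burn_in: int = 2_000
    thin: int = 10
    seed: int = 0
    mh_step: float = 0.3
    mh_target: float = 0.5
    tune_interval: int = 100
    pair_updates: bool = True

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_cycles):
            raise ValueError("burn_in must be smaller than n_cycles")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_stored(self) -> int:
        post = self.n_cycles - self.burn_in
        return (post + self.thin - 1) // self.thin


def sample_pi(delta: np.ndarray, beta_a: float = 1.0, beta_b: float = 100.0,
              rng: np.random.Generator | None = None) -> float:
    """Conjugate draw of pi1 given the indicator vector.

    pi1 | delta ~ Beta(beta_a + sum(delta), beta_b + m - sum(delta)).
    """
    delta = np.asarray(delta)
    if delta.size and not np.all((delta == 0) | (delta == 1)):
        raise ValueError("indicators must be binary")
    rng = rng if rng is not None else np.random.default_rng()
    nd = int(delta.sum())
    return float(rng.beta(beta_a + nd, beta_b + delta.size - nd))


class BayesianVariableSelection:
    """Whole-genome mixture regression with a pedigree polygenic term.

    Parameters
    ----------
    phenotypes
        pandas Series indexed by individual id (NaN = not phenotyped) or a
        plain array aligned with ``genotypes.ids``.
    genotypes
        :class:`~bvsgwas.data.GenotypeMatrix`, normally after QC.
    pedigree
        Optional :class:`~bvsgwas.pedigree.Pedigree`; when given, a
        polygenic effect with covariance A sigma_a^2 is fitted for every
        pedigree individual.  Every genotyped individual must appear in
        the pedigree.
    priors
        :class:`Priors`; defaults to the standard settings.
    dominance
        Append heterozygote-indicator columns sharing the same mixture
        prior as the additive columns (off by default).
    center
        Mean-centre the design columns (recommended; the intercept
        absorbs the shift).
    """

    def __init__(self, phenotypes, genotypes: GenotypeMatrix,
                 pedigree: Pedigree | None = None, *,
                 priors: Priors | None = None,
                 dominance: bool = False, center: bool = True):
        self.genotypes = genotypes
        self.pedigree = pedigree
        self.priors = priors if priors is not None else Priors()
        self.dominance = dominance
        self.center = center

        ids = genotypes.ids
        if isinstance(phenotypes, pd.Series):
            y_full = phenotypes.reindex(ids).to_numpy(dtype=float)
        else:
            y_full = np.asarray(phenotypes, dtype=float)
            if y_full.size != len(ids):
                raise ValueError("phenotype vector does not match genotyped individuals")
        self.y_full = y_full
        self.phenotyped = np.isfinite(y_full)
        self.y = y_full[self.phenotyped]

        coding = "additive+dominance" if dominance else "additive"
        self.design = code_design(genotypes, coding=coding, center=center)
        self.n_effects = self.design.shape[1]

        if pedigree is not None:
            index = {pid: i for i, pid in enumerate(pedigree.ids)}
            missing = [g for g in ids if g not in index]
            if missing:
                raise ValueError(f"genotyped individual {missing[0]!r} not in pedigree")
            self._geno_to_ped = np.array([index[g] for g in ids], dtype=np.int64)
            self._ainv = build_A_inverse(pedigree)
        else:
            self._geno_to_ped = None
            self._ainv = None

    @classmethod
    def from_simulation(cls, sim, *, qc_maf: float = 0.01, **kwargs
                        ) -> "BayesianVariableSelection":
        """Convenience constructor from a :class:`SimulatedPopulation`."""
        from .qc import filter_snps
        geno, _ = filter_snps(sim.genotypes, qc_maf)
        return cls(sim.phenotypes, geno, sim.pedigree, **kwargs)

    def fit(self, n_cycles: int = 52_000, burn_in: int = 2_000, thin: int = 10,
            seed: int = 0, *, config: MCMCConfig | None = None,
            update_mu: bool = True, update_pi: bool = True,
            update_variances: bool = True, mh_scale_move: bool = True,
            mu_init: float | None = None):
        """Run one MCMC chain and return a :class:`BVSResults`.

        The switch arguments freeze individual blocks (used by the
        sampler-validation suites); the defaults run the full model.
        """
        from .results import BVSResults

        cfg = config if config is not None else MCMCConfig(
            n_cycles=n_cycles, burn_in=burn_in, thin=thin, seed=seed)
        pri = self.priors
        n_p = self.y.size

        var_y = float(np.var(self.y)) if n_p > 1 else 1.0
        lb, ub = pri.var_bounds if pri.var_bounds is not None else (1e-8, 10.0 * var_y)
        sa_init = pri.sigma2_a_init if pri.sigma2_a_init is not None else \
            min(max(0.3 * var_y, lb), ub)
        se_init = pri.sigma2_e_init if pri.sigma2_e_init is not None else \
            min(max(0.7 * var_y, lb), ub)
        sg0_init = min(max(pri.sigma2_g0, lb), ub)

        if self.pedigree is not None:
            q = self.pedigree.n
            ainv = self._ainv.tocsr()
            phen_row = np.full(q, -1, dtype=np.int64)
            rows = np.flatnonzero(self.phenotyped)
            for pos, grow in enumerate(rows):
                phen_row[self._geno_to_ped[grow]] = pos
            indptr = ainv.indptr.astype(np.int64)
            indices = ainv.indices.astype(np.int64)
            data = ainv.data.astype(np.float64)
        else:
            phen_row = np.empty(0, dtype=np.int64)
            indptr = np.zeros(1, dtype=np.int64)
            indices = np.empty(0, dtype=np.int64)
            data = np.empty(0, dtype=np.float64)

        Xs = np.ascontiguousarray(self.design[self.phenotyped].T)
        xtx = np.einsum("kj,kj->k", Xs, Xs)
        mu0 = mu_init if mu_init is not None else (float(self.y.mean()) if n_p else 0.0)
        seed31 = int(np.random.SeedSequence(cfg.seed).generate_state(1)[0] % (2**31 - 1)) + 1

        (stored, pip, alpha_mean, a_mean, mu_mean, accept_rate, final_step,
         max_drift) = run_chain_kernel(
            np.ascontiguousarray(self.y, dtype=np.float64), Xs, xtx, phen_row,
            indptr, indices, data,
            mu0, pri.pi1, pri.beta_a, pri.beta_b,
            sg0_init, pri.variance_ratio, sa_init, se_init,
            lb, ub, lb, ub, lb, ub,
            cfg.n_cycles, cfg.burn_in, cfg.thin,
            cfg.mh_step, cfg.mh_target, cfg.tune_interval,
            seed31,
            1 if (update_mu and n_p > 0) else 0,
            1 if update_pi else 0,
            1 if (update_variances and self.pedigree is not None) else 0,
            1 if update_variances else 0,
            1 if mh_scale_move else 0,
            1 if cfg.pair_updates else 0,
        )
        if not np.all(np.isfinite(stored)):
            raise FloatingPointError("non-finite state encountered during sampling")
        scalars = pd.DataFrame(stored, columns=[
            "mu", "sigma2_a", "sigma2_e", "sigma2_g0", "sigma2_g1",
            "pi1", "var_snp", "n_large"])
        return BVSResults(
            model=self, config=cfg, scalars=scalars, pip=pip,
            snp_effect_mean=alpha_mean, polygenic_mean=a_mean,
            mu_mean=float(mu_mean), mh_accept_rate=float(accept_rate),
            mh_final_step=float(final_step), residual_drift=float(max_drift))
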
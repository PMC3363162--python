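"""Results object returned by :meth:`BayesianVariableSelection.fit`.

Carries the stored scalar draws and per-SNP / per-individual posterior
means, and derives everything downstream: posterior summaries with HPD
intervals and effective sample sizes, per-SNP Bayes factors and evidence
classes, heritability, genomic breeding values, QTL region calls and the
Manhattan plot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import diagnostics as dg
from .model import MCMCConfig

BF_CAP = 1.0e6


@dataclass
class BVSResults:
    model: object
    config: MCMCConfig
    scalars: pd.DataFrame           # thinned post-burn-in draws
    pip: np.ndarray                 # posterior inclusion probability per column
    snp_effect_mean: np.ndarray
    polygenic_mean: np.ndarray      # per pedigree individual (empty if no pedigree)
    mu_mean: float
    mh_accept_rate: float
    mh_final_step: float
    residual_drift: float

    # ------------------------------------------------------------------ scalars

    def h2_samples(self, include_snp: bool = True) -> np.ndarray:
        """Per-stored-cycle heritability.

        total (default): (sigma_a^2 + V_SNP) / (sigma_a^2 + V_SNP + sigma_e^2)
        with V_SNP the empirical variance of the fitted SNP genetic values
        across phenotyped individuals at that cycle; ``include_snp=False``
        gives the polygenic-only ratio sigma_a^2 / (sigma_a^2 + sigma_e^2).
        """
        sa = self.scalars["sigma2_a"].to_numpy()
        se = self.scalars["sigma2_e"].to_numpy()
        vs = self.scalars["var_snp"].to_numpy() if include_snp else 0.0
        return (sa + vs) / (sa + vs + se)

    def heritability(self, include_snp: bool = True) -> dict:
        h2 = self.h2_samples(include_snp)
        lo, hi = dg.hpd_interval(h2) if h2.size >= 100 else (np.nan, np.nan)
        return {"mean": float(h2.mean()), "sd": float(h2.std(ddof=1)),
                "hpd95_lo": lo, "hpd95_hi": hi}

    def summary(self, hpd_mass: float = 0.95) -> pd.DataFrame:
        """Posterior mean, sd, HPD bounds and ESS for every scalar parameter."""
        rows = {}
        for name in ["mu", "sigma2_a", "sigma2_e", "sigma2_g0", "sigma2_g1", "pi1"]:
            if name in ("sigma2_a",) and self.model.pedigree is None:
                continue
            x = self.scalars[name].to_numpy()
            lo, hi = dg.hpd_interval(x, hpd_mass) if x.size >= 100 else (np.nan, np.nan)
            ess = dg.effective_sample_size(x) if x.size >= 100 else np.nan
            rows[name] = [x.mean(), x.std(ddof=1), lo, hi, ess]
        for label, flag in (("h2_total", True), ("h2_polygenic", False)):
            if self.model.pedigree is None and not flag:
                continue
            x = self.h2_samples(flag)
            lo, hi = dg.hpd_interval(x, hpd_mass) if x.size >= 100 else (np.nan, np.nan)
            ess = dg.effective_sample_size(x) if x.size >= 100 else np.nan
            rows[label] = [x.mean(), x.std(ddof=1), lo, hi, ess]
        return pd.DataFrame.from_dict(
            rows, orient="index",
            columns=["mean", "sd", "hpd95_lo", "hpd95_hi", "ess"])

    # ------------------------------------------------------------------ SNPs

    def snp_table(self) -> pd.DataFrame:
        """One row per SNP: inclusion probability, effect, BF, evidence class.

        Saturated inclusion probabilities (p = 1) give an infinite Bayes
        factor, reported capped at 1e6 with ``bf_capped`` set.
        """
        g = self.model.genotypes
        m = g.n_snps
        pi1 = self.model.priors.pi1_prior_mean
        pip = self.pip[:m]  # dominance columns, when present, come after
        bf = np.array([dg.bayes_factor(min(p, 1.0), pi1) for p in pip])
        capped = ~np.isfinite(bf)
        bf = np.where(capped, BF_CAP, bf)
        cls = [dg.classify_evidence(b) for b in bf]
        return pd.DataFrame({
            "snp": g.snp_ids,
            "chrom": g.gmap.chrom,
            "pos_morgan": g.gmap.pos,
            "pip": pip,
            "effect_mean": self.snp_effect_mean[:m],
            "bf": bf,
            "bf_capped": capped,
            "evidence": cls,
        })

    def call_qtl(self, r2_threshold: float = 0.7, max_gap: float = 0.1,
                 linkage: str = "average"):
        """Group classified SNPs into putative QTL regions by LD blocks."""
        from .qtl import group_snps_to_qtl
        return group_snps_to_qtl(self.snp_table(), self.model.genotypes.codes,
                                 r2_threshold=r2_threshold, max_gap=max_gap,
                                 linkage=linkage)

    # ------------------------------------------------------------------ GEBV

    def predict_gebv(self) -> pd.DataFrame:
        """Posterior-mean genetic value per individual.

        GEBV_i = mean(a_i) + sum_k x_ik mean(alpha_k): the polygenic
        posterior mean (pedigree individuals; 0 without a pedigree) plus
        the SNP genetic value from the centred design columns.  Defined
        for every genotyped individual, phenotyped or not.
        """
        mdl = self.model
        snp_part = mdl.design @ self.snp_effect_mean
        if mdl.pedigree is not None:
            poly = self.polygenic_mean[mdl._geno_to_ped]
        else:
            poly = np.zeros_like(snp_part)
        return pd.DataFrame({
            "id": mdl.genotypes.ids,
            "gebv": poly + snp_part,
            "phenotyped": mdl.phenotyped,
        })

    # ------------------------------------------------------------------ plots

    def plot_manhattan(self, ax=None):
        """log10 Bayes factor by genome position with the evidence thresholds."""
        import matplotlib.pyplot as plt

        tab = self.snp_table()
        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        offset = 0.0
        ticks = []
        for c in np.unique(tab["chrom"]):
            sel = tab[tab["chrom"] == c]
            x = sel["pos_morgan"].to_numpy() + offset
            ax.scatter(x, np.log10(np.maximum(sel["bf"], 1e-3)), s=6,
                       color="C0" if c % 2 else "C2")
            ticks.append((offset + x[-1]) / 2 if len(x) else offset)
            offset = x[-1] if len(x) else offset
        ax.axhline(np.log10(dg.BF_STRONG), color="k", lw=0.8)
        ax.axhline(np.log10(dg.BF_PUTATIVE), color="k", lw=0.8, ls="--")
        ax.set_xlabel("genome position (Morgan, cumulative)")
        ax.set_ylabel("log10 BF")
        return ax
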
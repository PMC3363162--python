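"""End-to-end driver: simulate -> QC -> fit -> summarize -> call QTL ->
predict -> validate, writing every interface file plus a run manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import io as bio
from .config import RunConfig
from .model import BayesianVariableSelection, Priors
from .qc import filter_snps
from .qtl import calls_to_frame, validate_gebv
from .simulate import simulate_population


def _param_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the whole analysis; returns the run directory."""
    cfg = config.resolved()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- data: external files or the simulator
    truth = None
    if cfg.genotype_path:
        geno = bio.read_genotypes_tsv(cfg.genotype_path, cfg.map_path)
        ped = bio.read_pedigree_tsv(cfg.pedigree_path) if cfg.pedigree_path else None
        phen = bio.read_phenotypes_tsv(cfg.phenotype_path)
    else:
        sim = simulate_population(cfg.sim, seed=cfg.seed)
        geno, ped, phen, truth = sim.genotypes, sim.pedigree, sim.phenotypes, sim.truth
        bio.write_genotypes_tsv(geno, out / "genotypes.tsv")
        bio.write_map_tsv(geno.gmap, geno.snp_ids, out / "map.tsv")
        bio.write_pedigree_tsv(ped, out / "pedigree.tsv")
        bio.write_phenotypes_tsv(truth.ids, truth.phenotype, out / "phenotypes.tsv")
        bio.write_truth_tsv(truth, out / "truth.tsv")
        bio.write_architecture_json(sim.architecture, geno.snp_ids,
                                    out / "architecture.json")

    # ---- QC
    geno_qc, report = filter_snps(geno, cfg.maf_threshold)
    report.to_frame().assign(snp=geno.snp_ids).to_csv(
        out / "qc_report.tsv", sep="\t", index=False)

    # ---- fit
    priors = Priors(pi0=cfg.pi0, variance_ratio=cfg.variance_ratio)
    model = BayesianVariableSelection(phen, geno_qc, ped, priors=priors,
                                      dominance=cfg.dominance)
    res = model.fit(n_cycles=cfg.n_cycles, burn_in=cfg.burn_in, thin=cfg.thin,
                    seed=cfg.seed)

    # ---- summaries
    res.scalars.to_csv(out / "chain_scalars.tsv", sep="\t", index=False)
    res.summary().to_csv(out / "summary.tsv", sep="\t", index_label="parameter")
    snp_tab = res.snp_table()
    snp_tab.to_csv(out / "snp_summary.tsv", sep="\t", index=False)

    # ---- QTL calls and prediction
    calls = res.call_qtl(r2_threshold=cfg.r2_threshold, max_gap=cfg.max_gap)
    calls_to_frame(calls).to_csv(out / "qtl_calls.tsv", sep="\t", index=False)
    gebv = res.predict_gebv()
    gebv.to_csv(out / "gebv.tsv", sep="\t", index=False)

    validation = None
    if truth is not None:
        validation = validate_gebv(gebv, truth, subset="unphenotyped")
        Path(out / "validation.tsv").write_text(
            "correlation\tslope\tn\n"
            f"{validation['correlation']:.6f}\t{validation['slope']:.6f}\t{validation['n']}\n")

    bio.write_manifest(
        out / "manifest.json",
        seed=cfg.seed, scale=cfg.scale, param_hash=_param_hash(cfg),
        n_snps_input=geno.n_snps, n_snps_retained=geno_qc.n_snps,
        n_individuals=geno.n_individuals,
        n_phenotyped=int(np.isfinite(phen.to_numpy(dtype=float)).sum()),
        mh_accept_rate=res.mh_accept_rate,
        validation=validation,
    )
    return out
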
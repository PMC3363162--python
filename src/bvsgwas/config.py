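"""Run configuration for the end-to-end pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .simulate import PopSimConfig


@dataclass(frozen=True)
class RunConfig:
    """All pipeline settings with the standard analysis defaults.

    Model defaults: pi0 = 0.98, variance ratio 1:100, 52,000 MCMC cycles
    with 2,000 burn-in, MAF filter 0.01, BF thresholds 10 / 3.2, LD
    grouping at r^2 >= 0.7, simulated trait heritability 0.30.  The
    ``desk`` scale preset shrinks the simulated design (5 dams/sire, 6
    offspring/dam, 250 SNPs/chromosome) and the chain (10,000 cycles).
    """

    out_dir: str = "run"
    seed: int = 0
    scale: str = "full"  # full | desk

    # optional external inputs; when None the simulator provides the data
    genotype_path: str | None = None
    map_path: str | None = None
    pedigree_path: str | None = None
    phenotype_path: str | None = None

    sim: PopSimConfig = field(default_factory=PopSimConfig)

    maf_threshold: float = 0.01
    pi0: float = 0.98
    variance_ratio: float = 100.0
    dominance: bool = False
    n_cycles: int = 52_000
    burn_in: int = 2_000
    thin: int = 10

    bf_strong: float = 10.0
    bf_putative: float = 3.2
    r2_threshold: float = 0.7
    max_gap: float = 0.1

    def __post_init__(self):
        if self.scale not in ("full", "desk"):
            raise ValueError("scale must be 'full' or 'desk'")
        if not (0 <= self.burn_in < self.n_cycles):
            raise ValueError("burn_in must be smaller than n_cycles")
        if not (0.0 <= self.maf_threshold < 0.5):
            raise ValueError("maf_threshold must lie in [0, 0.5)")

    def resolved(self) -> "RunConfig":
        """Apply the scale preset to the simulation and chain settings."""
        if self.scale == "desk":
            return replace(self, sim=self.sim.desk(),
                           n_cycles=min(self.n_cycles, 10_000),
                           burn_in=min(self.burn_in, 2_000))
        return self

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        sim_raw = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim_raw:
            cfg = replace(cfg, sim=PopSimConfig(**sim_raw))
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["sim"]["qtl_spec"] = [list(e.values()) if isinstance(e, dict) else list(e)
                                for e in d["sim"]["qtl_spec"]]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
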
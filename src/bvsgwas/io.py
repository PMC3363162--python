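"""Readers and writers for the plain-text interchange formats.

Genotypes travel either as a TSV (rows = individuals, header = SNP ids,
codes 0/1/2, NA = missing) with a companion map TSV, or as PLINK-style
.ped/.map with letter alleles (map positions in centiMorgan).  Pedigree,
phenotype and truth files are simple TSVs; "0" marks an unknown parent
and "NA" a missing value.  Every writer here has a matching reader and
round-trips are lossless for the fields defined.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data import GeneticMap, GenotypeMatrix
from .pedigree import Pedigree
from .simulate import QTLArchitecture, TrueValues

# ---------------------------------------------------------------- genotype TSV


def write_genotypes_tsv(g: GenotypeMatrix, path) -> None:
    df = g.to_frame().astype(object)
    df[df == -1] = "NA"
    df.to_csv(path, sep="\t", index_label="id")


def write_map_tsv(gmap: GeneticMap, snp_ids, path) -> None:
    pd.DataFrame({"snp": snp_ids, "chrom": gmap.chrom,
                  "pos_morgan": gmap.pos}).to_csv(path, sep="\t", index=False)


def read_map_tsv(path) -> tuple[GeneticMap, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return GeneticMap(df["chrom"].to_numpy(), df["pos_morgan"].to_numpy()), \
        [str(s) for s in df["snp"]]


def read_genotypes_tsv(path, map_path) -> GenotypeMatrix:
    gmap, snp_ids = read_map_tsv(map_path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if list(df.columns) != snp_ids:
        raise ValueError("genotype columns do not match the SNP map")
    ids = [str(i) for i in df.index]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate individual id in genotype file")
    vals = df.to_numpy(dtype=float)
    codes = np.where(np.isnan(vals), -1, vals)
    bad = ~np.isin(codes, (-1, 0, 1, 2))
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid genotype code {vals[i, j]:g} for individual {ids[i]!r} "
            f"at SNP {snp_ids[j]!r} (row {i + 2} of {path})")
    return GenotypeMatrix(codes.astype(np.int8), gmap, ids, snp_ids)


# ---------------------------------------------------------------- PLINK-style


def write_ped_map(g: GenotypeMatrix, prefix) -> None:
    """PLINK-style .ped/.map; alleles A (reference) / B (counted)."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for sid, c, p in zip(g.snp_ids, g.gmap.chrom, g.gmap.pos):
            fh.write(f"{c}\t{sid}\t{p * 100.0:.6f}\t{int(round(p * 1e6))}\n")
    code_to_alleles = {0: "A A", 1: "A B", 2: "B B", -1: "0 0"}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, ind in enumerate(g.ids):
            alleles = " ".join(code_to_alleles[int(c)] for c in g.codes[i])
            fh.write(f"FAM {ind} 0 0 0 -9 {alleles}\n")


def read_ped_map(prefix) -> GenotypeMatrix:
    """Read .ped/.map; codes count the non-first-seen allele per SNP."""
    prefix = Path(prefix)
    rows = []
    with open(prefix.with_suffix(".map")) as fh:
        for line in fh:
            c, sid, cm, _bp = line.split()
            rows.append((int(c), str(sid), float(cm) / 100.0))
    gmap = GeneticMap(np.array([r[0] for r in rows]), np.array([r[2] for r in rows]))
    snp_ids = [r[1] for r in rows]
    m = len(rows)
    ids = []
    allele0: list[str | None] = [None] * m
    raw: list[list[tuple[str, str]]] = []
    with open(prefix.with_suffix(".ped")) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise ValueError(f"line {ln}: expected {6 + 2 * m} fields, got {len(parts)}")
            ids.append(parts[1])
            pairs = [(parts[6 + 2 * k], parts[7 + 2 * k]) for k in range(m)]
            for k, (a, b) in enumerate(pairs):
                for al in (a, b):
                    if al != "0" and allele0[k] is None:
                        allele0[k] = al
            raw.append(pairs)
    codes = np.full((len(ids), m), -1, dtype=np.int8)
    for i, pairs in enumerate(raw):
        for k, (a, b) in enumerate(pairs):
            if a == "0" or b == "0":
                continue
            codes[i, k] = int(a != allele0[k]) + int(b != allele0[k])
    return GenotypeMatrix(codes, gmap, ids, snp_ids)


# ---------------------------------------------------------------- pedigree etc.


def write_pedigree_tsv(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, sep="\t", index=False)


def read_pedigree_tsv(path) -> Pedigree:
    return Pedigree.from_frame(pd.read_csv(path, sep="\t", dtype=str))


def write_phenotypes_tsv(ids, phenotype: np.ndarray, path) -> None:
    out = pd.DataFrame({"id": ids, "phenotype": phenotype})
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    return pd.Series(df["phenotype"].to_numpy(dtype=float),
                     index=[str(i) for i in df["id"]], name="phenotype")


def write_truth_tsv(truth: TrueValues, path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


def read_truth_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"],
                       dtype={"id": str})


def write_architecture_json(arch: QTLArchitecture, snp_ids, path) -> None:
    entries = [{
        "snps": [snp_ids[k] for k in q.snp_idx],
        "snp_idx": list(q.snp_idx),
        "mode": q.mode,
        "effect": q.effect,
        "parent_of_origin": q.parent_of_origin,
    } for q in arch.qtls]
    Path(path).write_text(json.dumps(entries, indent=1))


def write_sparse_coo(mat, path) -> None:
    """Coordinate-format text export of a (sparse) symmetric matrix."""
    coo = sp.coo_matrix(mat)
    with open(path, "w") as fh:
        fh.write(f"# {coo.shape[0]} {coo.shape[1]} {coo.nnz}\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i}\t{j}\t{v:.12g}\n")


def write_manifest(path, **fields) -> None:
    import platform

    meta = {"python": platform.python_version()}
    meta.update(fields)
    Path(path).write_text(json.dumps(meta, indent=1, sort_keys=True, default=str))
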
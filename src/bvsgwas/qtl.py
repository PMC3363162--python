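"""QTL region calling from classified SNPs, and breeding-value validation.

Significant/putative SNPs are grouped per chromosome by agglomerative
clustering on their pairwise genotype-correlation LD (r^2): clusters are
merged while the linkage score (mean cross-cluster r^2 by default) stays
at or above the threshold and the map gap between clusters stays within
``max_gap``.  Grouping SNPs by LD can split or merge true QTL — a known
limitation of the approach, not corrected here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class QTLCall:
    region: int
    chrom: int
    members: tuple[str, ...]
    member_idx: tuple[int, ...]
    span_morgan: float
    peak_snp: str
    peak_bf: float
    evidence: str  # significant if any member is, else putative

    @property
    def n_members(self) -> int:
        return len(self.members)


def ld_r2(col_a: np.ndarray, col_b: np.ndarray) -> float:
    """Composite (phase-free) LD: squared Pearson correlation of codes."""
    a = np.asarray(col_a, dtype=float)
    b = np.asarray(col_b, dtype=float)
    if a.std() == 0.0 or b.std() == 0.0:
        raise ValueError("monomorphic column has undefined LD")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _linkage_score(r2: np.ndarray, ca: list[int], cb: list[int], how: str) -> float:
    block = r2[np.ix_(ca, cb)]
    if how == "average":
        return float(block.mean())
    if how == "complete":
        return float(block.min())
    if how == "single":
        return float(block.max())
    raise ValueError(f"unknown linkage {how!r}")


def cluster_by_ld(r2: np.ndarray, pos: np.ndarray, *, r2_threshold: float = 0.7,
                  max_gap: float = 0.1, linkage: str = "average") -> list[list[int]]:
    """Agglomerate SNPs on one chromosome into LD blocks.

    Greedy merging of the highest-scoring admissible cluster pair; a pair
    is admissible while its linkage score (mean cross r^2 by default)
    stays >= ``r2_threshold`` and the closest members are <= ``max_gap``
    Morgan apart.  Returns clusters ordered by position.
    """
    k = r2.shape[0]
    clusters: list[list[int]] = [[i] for i in range(k)]
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                gap = min(abs(pos[a] - pos[b])
                          for a in clusters[i] for b in clusters[j])
                if gap > max_gap:
                    continue
                score = _linkage_score(r2, clusters[i], clusters[j], linkage)
                if score >= r2_threshold and (best is None or score > best[0]):
                    best = (score, i, j)
        if best is None:
            break
        _, i, j = best
        clusters[i] = sorted(clusters[i] + clusters[j])
        del clusters[j]
    clusters.sort(key=lambda cl: pos[cl[0]])
    return clusters


def group_snps_to_qtl(snp_table: pd.DataFrame, codes: np.ndarray, *,
                      r2_threshold: float = 0.7, max_gap: float = 0.1,
                      linkage: str = "average",
                      classes: tuple[str, ...] = ("significant", "putative"),
                      ) -> list[QTLCall]:
    """Group classified SNPs into QTL regions.

    ``snp_table`` is the per-SNP frame from :meth:`BVSResults.snp_table`
    (columns snp, chrom, pos_morgan, bf, evidence); ``codes`` the full
    genotype code matrix aligned with it.  Returns one
    :class:`QTLCall` per region; grouping is invariant to input row
    order (rows are sorted by chromosome and position first).
    """
    tab = snp_table[snp_table["evidence"].isin(classes)].copy()
    tab["_col"] = np.arange(len(snp_table))[snp_table["evidence"].isin(classes)]
    tab = tab.sort_values(["chrom", "pos_morgan"]).reset_index(drop=True)
    calls: list[QTLCall] = []
    region = 0
    for c in sorted(tab["chrom"].unique()):
        sub = tab[tab["chrom"] == c].reset_index(drop=True)
        k = len(sub)
        cols = sub["_col"].to_numpy()
        pos = sub["pos_morgan"].to_numpy()
        X = codes[:, cols].astype(float)
        r2 = np.corrcoef(X.T) ** 2 if k > 1 else np.ones((1, 1))
        r2 = np.nan_to_num(np.atleast_2d(r2), nan=0.0)
        clusters = cluster_by_ld(r2, pos, r2_threshold=r2_threshold,
                                 max_gap=max_gap, linkage=linkage)
        for cl in clusters:
            region += 1
            bfs = sub.loc[cl, "bf"].to_numpy()
            peak = cl[int(np.argmax(bfs))]
            ev = "significant" if (sub.loc[cl, "evidence"] == "significant").any() \
                else "putative"
            calls.append(QTLCall(
                region=region, chrom=int(c),
                members=tuple(sub.loc[cl, "snp"]),
                member_idx=tuple(int(x) for x in cols[cl]),
                span_morgan=float(pos[cl[-1]] - pos[cl[0]]),
                peak_snp=str(sub.loc[peak, "snp"]),
                peak_bf=float(bfs.max()),
                evidence=ev,
            ))
    return calls


def calls_to_frame(calls: list[QTLCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "region": c.region, "chrom": c.chrom, "n_members": c.n_members,
        "span_morgan": c.span_morgan, "peak_snp": c.peak_snp,
        "peak_bf": c.peak_bf, "evidence": c.evidence,
        "members": ",".join(c.members),
    } for c in calls])


def validate_gebv(gebv: pd.DataFrame, truth, subset: str = "unphenotyped") -> dict:
    """Accuracy of estimated against simulated breeding values.

    Pearson correlation plus the regression slope of true on estimated
    values (a slope near 1 indicates unbiased dispersion).  ``subset``:
    "unphenotyped" (default), "phenotyped" or "all".
    """
    tf = truth.to_frame() if hasattr(truth, "to_frame") else truth
    merged = gebv.merge(tf[["id", "true_bv"]], on="id")
    if subset == "unphenotyped":
        merged = merged[~merged["phenotyped"]]
    elif subset == "phenotyped":
        merged = merged[merged["phenotyped"]]
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")
    if len(merged) < 3:
        raise ValueError("need at least 3 overlapping individuals")
    x = merged["gebv"].to_numpy()
    t = merged["true_bv"].to_numpy()
    r = float(np.corrcoef(x, t)[0, 1])
    xc = x - x.mean()
    slope = float(np.dot(t - t.mean(), xc) / np.dot(xc, xc)) if np.any(xc) else np.nan
    return {"correlation": r, "slope": slope, "n": int(len(merged))}
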
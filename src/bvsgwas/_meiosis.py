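"""Numba kernels for meiosis and gene drop.

Recombination follows the Haldane model: per chromosome the crossover
count is Poisson(length in Morgan) with crossover positions uniform and
no interference; the starting parental strand is chosen at random.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _gamete(hap0, hap1, offsets, pos, lens, out):
    """Recombine one parent's two haplotypes into ``out``; returns crossover count."""
    total = 0
    n_chrom = lens.size
    for c in range(n_chrom):
        a, b = offsets[c], offsets[c + 1]
        L = lens[c]
        k = np.random.poisson(L) if L > 0.0 else 0
        xpos = np.sort(np.random.uniform(0.0, L, k)) if k > 0 else np.empty(0)
        cur = np.random.randint(0, 2)
        xi = 0
        for j in range(a, b):
            while xi < k and xpos[xi] < pos[j]:
                cur = 1 - cur
                xi += 1
            out[j] = hap0[j] if cur == 0 else hap1[j]
        total += k
    return total


@njit(cache=True)
def random_mating(haps, n_generations, n_out, offsets, pos, lens, seed):
    """Evolve a diploid population by discrete-generation random mating.

    ``haps`` is (N, 2, m) uint8.  Each generation N offspring are produced
    from random (non-self) parent pairs; after ``n_generations`` the
    population is expanded/contracted to ``n_out`` individuals by one more
    round of random mating.  Returns (n_out, 2, m).
    """
    np.random.seed(seed)
    N = haps.shape[0]
    m = haps.shape[2]
    cur = haps.copy()
    for _ in range(n_generations):
        nxt = np.empty((N, 2, m), dtype=np.uint8)
        for i in range(N):
            s = np.random.randint(0, N)
            d = np.random.randint(0, N)
            while d == s and N > 1:
                d = np.random.randint(0, N)
            _gamete(cur[s, 0], cur[s, 1], offsets, pos, lens, nxt[i, 0])
            _gamete(cur[d, 0], cur[d, 1], offsets, pos, lens, nxt[i, 1])
        cur = nxt
    out = np.empty((n_out, 2, m), dtype=np.uint8)
    for i in range(n_out):
        s = np.random.randint(0, N)
        d = np.random.randint(0, N)
        while d == s and N > 1:
            d = np.random.randint(0, N)
        _gamete(cur[s, 0], cur[s, 1], offsets, pos, lens, out[i, 0])
        _gamete(cur[d, 0], cur[d, 1], offsets, pos, lens, out[i, 1])
    return out


@njit(cache=True)
def sample_crossover_counts(hap0, hap1, offsets, pos, lens, n_meioses, seed):
    """Crossover count for each of ``n_meioses`` simulated gametes."""
    np.random.seed(seed)
    out = np.empty(pos.size, dtype=np.uint8)
    counts = np.empty(n_meioses, dtype=np.int64)
    for i in range(n_meioses):
        counts[i] = _gamete(hap0, hap1, offsets, pos, lens, out)
    return counts


@njit(cache=True)
def drop_haplotypes(sire, dam, founder_haps, offsets, pos, lens, seed):
    """Gene-drop founder haplotypes down a topologically ordered pedigree.

    Founders (both parents unknown) consume consecutive haplotype pairs
    from ``founder_haps`` (2*n_founders, m); every other individual gets a
    recombinant paternal gamete from its sire and maternal gamete from its
    dam.  Returns (haps (n, 2, m), total crossover count).
    """
    np.random.seed(seed)
    n = sire.size
    m = pos.size
    haps = np.zeros((n, 2, m), dtype=np.uint8)
    nf = 0
    xovers = 0
    for i in range(n):
        if sire[i] < 0 and dam[i] < 0:
            haps[i, 0] = founder_haps[2 * nf]
            haps[i, 1] = founder_haps[2 * nf + 1]
            nf += 1
        else:
            xovers += _gamete(haps[sire[i], 0], haps[sire[i], 1], offsets, pos, lens, haps[i, 0])
            xovers += _gamete(haps[dam[i], 0], haps[dam[i], 1], offsets, pos, lens, haps[i, 1])
    return haps, xovers


def map_arrays(chrom: np.ndarray, pos: np.ndarray, chrom_lengths=None):
    """Flattened per-chromosome (offsets, pos, lens) arrays for the kernels."""
    chroms = np.unique(chrom)
    offsets = np.zeros(chroms.size + 1, dtype=np.int64)
    for i, c in enumerate(chroms):
        offsets[i + 1] = offsets[i] + np.sum(chrom == c)
    if chrom_lengths is None:
        lens = np.ones(chroms.size, dtype=np.float64)
    else:
        lens = np.asarray(chrom_lengths, dtype=np.float64)
        if lens.size != chroms.size:
            raise ValueError("one length per chromosome required")
    return offsets, np.ascontiguousarray(pos, dtype=np.float64), lens
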
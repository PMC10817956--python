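"""Independent reference implementations used only by the test suite.

Each oracle is written from the defining formula or by brute-force
enumeration, deliberately avoiding the package's own code paths.
"""

from __future__ import annotations

import itertools
import math
from typing import List, Sequence, Tuple

import numpy as np


def hwe_enumeration(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE p by full enumeration with rational factorial arithmetic."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa  # minor-ish allele count (symmetry makes it moot)
    n_A = 2 * n - n_a

    def prob(het: int) -> float:
        hom_a = (n_a - het) // 2
        hom_A = n - het - hom_a
        # multinomial probability conditional on allele counts
        num = (
            math.factorial(n)
            / (math.factorial(hom_A) * math.factorial(hom_a) * math.factorial(het))
            * 2**het
        )
        den = math.factorial(2 * n) / (math.factorial(n_A) * math.factorial(n_a))
        return num / den

    lo = n_a % 2
    hets = range(lo, min(n_a, 2 * n - n_a) + 1, 2)
    probs = {h: prob(h) for h in hets}
    p_obs = probs[n_Aa]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12)))


def wc_fst_two_pops(
    genotypes_a: np.ndarray, genotypes_b: np.ndarray
) -> Tuple[float, float, float, float]:
    """Weir & Cockerham (1984) a, b, c for one biallelic site and two
    populations, written directly from the published estimator with scalar
    arithmetic.  Genotype vectors are dosages 0/1/2 (no missing)."""
    r = 2
    n_i = [len(genotypes_a), len(genotypes_b)]
    p_i = [np.mean(genotypes_a) / 2.0, np.mean(genotypes_b) / 2.0]
    h_i = [
        np.mean(np.asarray(genotypes_a) == 1),
        np.mean(np.asarray(genotypes_b) == 1),
    ]
    nbar = sum(n_i) / r
    nc = (r * nbar - sum(n**2 for n in n_i) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p in zip(n_i, p_i)) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(n_i, h_i)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2.0
    tot = a + b + c
    fst = a / tot if abs(tot) > 0 else float("nan")
    return a, b, c, fst


def pairwise_pi(haplotypes: np.ndarray, span_bp: int) -> float:
    """Window pi by brute-force comparison of every haplotype pair at every
    site (missing coded -1 drops the pair at that site)."""
    H = np.asarray(haplotypes)
    n = H.shape[0]
    total = 0.0
    for s in range(H.shape[1]):
        col = H[:, s]
        diffs = pairs = 0
        for i, j in itertools.combinations(range(n), 2):
            if col[i] < 0 or col[j] < 0:
                continue
            pairs += 1
            diffs += int(col[i] != col[j])
        if pairs:
            total += diffs / pairs
    return total / span_bp


def ehh_by_pairs(haps: np.ndarray, core: int, j: int) -> float:
    """EHH between the core and site j (inclusive) by explicit pair counting
    over the spanned sites, excluding the core's own allele."""
    H = np.asarray(haps)
    lo, hi = (core + 1, j) if j > core else (j, core - 1)
    span = H[:, lo : hi + 1]
    n = H.shape[0]
    ident = 0
    for a, b in itertools.combinations(range(n), 2):
        if np.array_equal(span[a], span[b]):
            ident += 1
    return ident / (n * (n - 1) / 2)


def trapezoid_quadrature(curve: Sequence[Tuple[float, float]]) -> float:
    """Plain scalar trapezoid rule over a piecewise-linear decay curve."""
    area = 0.0
    for (d0, e0), (d1, e1) in zip(curve[:-1], curve[1:]):
        area += (d1 - d0) * (e0 + e1) / 2.0
    return area


def sweep_line_merge(
    intervals: List[Tuple[str, int, int]],
) -> List[Tuple[str, int, int]]:
    """bedtools-style merge (overlap or book-ended) via sorted sweep."""
    out: List[Tuple[str, int, int]] = []
    for contig in sorted({c for c, _, _ in intervals}):
        ivs = sorted((s, e) for c, s, e in intervals if c == contig)
        cur_s, cur_e = None, None
        for s, e in ivs:
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((contig, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            out.append((contig, cur_s, cur_e))
    return out


def brute_overlaps(
    regions: List[Tuple[str, int, int]], genes: List[Tuple[str, str, int, int]]
) -> dict:
    """All-pairs >=1 bp interval intersection (half-open)."""
    out = {}
    for k, (rc, rs, re) in enumerate(regions):
        out[k] = sorted(
            gid for gid, gc, gs, ge in genes if gc == rc and gs < re and ge > rs
        )
    return out
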
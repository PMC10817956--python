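"""Diversity and structure statistics on sliding genomic windows.

Implements windowed nucleotide diversity (pi), per-sample inbreeding F,
the Weir & Cockerham (1984) two-population Fst estimator with its a/b/c
variance components and the ratio-of-sums "weighted" window form, pairwise
LD r-squared with distance-binned decay curves, plink-style greedy LD
pruning, and PCA of Patterson-scaled genotypes.

Windows are 0-based half-open, built on a fixed grid (default 20 kb with a
10 kb step, the geometry used throughout the scan modules).  Window tables
are plain :class:`pandas.DataFrame` objects with at least the columns
``contig, start, end, n_snps``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .vcfio import GenotypeMatrix

__all__ = [
    "make_windows",
    "window_site_indices",
    "nucleotide_diversity",
    "inbreeding_f",
    "wc_fst_components",
    "windowed_weighted_fst",
    "ld_r2",
    "ld_decay",
    "LDDecayCurve",
    "ld_prune",
    "pca",
]


def make_windows(
    contig_lengths: Dict[str, int], size: int = 20_000, step: int = 10_000
) -> pd.DataFrame:
    """Sliding-window grid: starts at 0, step, 2*step, ... while start < length.

    The last window of a contig is truncated at the contig end.
    """
    if not (size >= step > 0):
        raise ValueError("need size >= step > 0")
    rows = []
    for contig, length in contig_lengths.items():
        start = 0
        while start < length:
            rows.append((contig, start, min(start + size, length)))
            start += step
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


def window_site_indices(
    windows: pd.DataFrame, contig: np.ndarray, pos0: np.ndarray
) -> List[np.ndarray]:
    """Variant indices falling in each window ([start, end), same contig)."""
    out = []
    for w in windows.itertuples(index=False):
        on_contig = np.flatnonzero(contig == w.contig)
        p = pos0[on_contig]
        lo = np.searchsorted(p, w.start, side="left")
        hi = np.searchsorted(p, w.end, side="left")
        out.append(on_contig[lo:hi])
    return out


def _site_pi(gm: GenotypeMatrix) -> np.ndarray:
    """Per-site pairwise-difference proportion c_ref*c_alt / C(n, 2)."""
    c_ref, c_alt = gm.allele_counts()
    n = c_ref + c_alt
    pairs = n * (n - 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(pairs > 0, c_ref * c_alt / np.maximum(pairs, 1e-300), 0.0)


def nucleotide_diversity(gm_pop: GenotypeMatrix, windows: pd.DataFrame) -> pd.DataFrame:
    """Windowed pi: sum of per-site pairwise-difference proportions divided by
    the full window span in bp (the VCFtools ``--window-pi`` convention —
    not by the number of called sites; noted in the ``denominator`` column).
    """
    site_pi = _site_pi(gm_pop)
    idx = window_site_indices(windows, gm_pop.contig, gm_pop.pos0)
    out = windows.copy()
    n_snps, pis, flags = [], [], []
    for w, sites in zip(windows.itertuples(index=False), idx):
        span = w.end - w.start
        called = sites[(gm_pop.dosage[:, sites] >= 0).any(axis=0)] if sites.size else sites
        n_snps.append(int(sites.size))
        pis.append(float(site_pi[sites].sum()) / span)
        flags.append(called.size == 0)
    out["n_snps"] = n_snps
    out["pi"] = pis
    out["no_called_sites"] = flags
    out.attrs["denominator"] = "window_span_bp"
    return out


def inbreeding_f(gm_pop: GenotypeMatrix) -> pd.DataFrame:
    """Per-sample inbreeding coefficient, method-of-moments on homozygosity.

    F = (O_hom - E_hom) / (L_called - E_hom) per sample, with the per-site
    expected homozygosity 1 - 2p(1-p) * 2n/(2n-1) computed from the sample
    allele frequency (small-sample corrected, the VCFtools ``--het`` form).
    Samples with no called sites or zero denominator get NaN and a flag.
    """
    if gm_pop.n_samples < 2:
        raise ValueError("inbreeding F needs >= 2 samples for allele frequencies")
    c_ref, c_alt = gm_pop.allele_counts()
    tot = c_ref + c_alt  # called allele count = 2n at each site
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, c_alt / np.maximum(tot, 1), np.nan)
        corr = np.where(tot > 1, tot / np.maximum(tot - 1.0, 1e-300), np.nan)
    e_hom_site = 1.0 - 2.0 * p * (1.0 - p) * corr

    called = gm_pop.dosage >= 0
    usable = called & np.isfinite(e_hom_site) & (tot > 1)
    o_hom = (usable & ((gm_pop.dosage == 0) | (gm_pop.dosage == 2))).sum(axis=1)
    e_hom = np.where(usable, e_hom_site, 0.0).sum(axis=1)
    n_called = usable.sum(axis=1)
    denom = n_called - e_hom
    with np.errstate(invalid="ignore", divide="ignore"):
        F = np.where(np.abs(denom) > 1e-12, (o_hom - e_hom) / denom, np.nan)
    return pd.DataFrame(
        {
            "sample": gm_pop.samples,
            "O_hom": o_hom,
            "E_hom": e_hom,
            "n_sites": n_called,
            "F": F,
            "undefined": ~np.isfinite(F),
        }
    )


def _pop_site_summaries(gm: GenotypeMatrix):
    """(n called diploids, alt freq, observed het proportion) per site."""
    called = gm.dosage >= 0
    n = called.sum(axis=0).astype(np.float64)
    alt = np.where(gm.dosage > 0, gm.dosage, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
        h = np.where(n > 0, (gm.dosage == 1).sum(axis=0) / np.maximum(n, 1), np.nan)
    return n, p, h


def wc_fst_components(
    nA: np.ndarray,
    pA: np.ndarray,
    hA: np.ndarray,
    nB: np.ndarray,
    pB: np.ndarray,
    hB: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) variance components for two populations.

    Inputs are per-site arrays: sample sizes in diploids, ALT allele
    frequencies and observed heterozygote proportions for each population.
    Returns (a, b, c, fst_site); sites where a+b+c = 0 (monomorphic across
    both) yield NaN fst and should be excluded from sums.
    """
    nA = np.asarray(nA, dtype=np.float64)
    nB = np.asarray(nB, dtype=np.float64)
    pA = np.asarray(pA, dtype=np.float64)
    pB = np.asarray(pB, dtype=np.float64)
    hA = np.asarray(hA, dtype=np.float64)
    hB = np.asarray(hB, dtype=np.float64)

    r = 2.0
    nbar = (nA + nB) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (nA**2 + nB**2) / (r * nbar)) / (r - 1.0)
        pbar = (nA * pA + nB * pB) / (r * nbar)
        s2 = (nA * (pA - pbar) ** 2 + nB * (pB - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (nA * hA + nB * hB) / (r * nbar)

        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - s2 * (r - 1.0) / r
            - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
        tot = a + b + c
        fst = np.where(np.abs(tot) > 1e-300, a / tot, np.nan)
    bad = (nA < 1) | (nB < 1) | ~np.isfinite(pA) | ~np.isfinite(pB)
    fst = np.where(bad, np.nan, fst)
    return a, b, c, fst


def windowed_weighted_fst(
    gm_A: GenotypeMatrix,
    gm_B: GenotypeMatrix,
    windows: pd.DataFrame,
    min_snps: int = 1,
) -> pd.DataFrame:
    """Windowed weighted Fst: ratio of sums sum(a)/sum(a+b+c) over the
    window's usable sites (not a mean of per-site ratios).

    A site is usable when both populations have called genotypes and the
    site is polymorphic somewhere (a+b+c > 0).  Windows with fewer than
    ``min_snps`` usable sites are flagged undefined.
    """
    if gm_A.n_variants != gm_B.n_variants:
        raise ValueError("panels must share a variant grid")
    nA, pA, hA = _pop_site_summaries(gm_A)
    nB, pB, hB = _pop_site_summaries(gm_B)
    a, b, c, fst_site = wc_fst_components(nA, pA, hA, nB, pB, hB)
    usable = np.isfinite(fst_site)

    idx = window_site_indices(windows, gm_A.contig, gm_A.pos0)
    out = windows.copy()
    vals, counts = [], []
    for sites in idx:
        use = sites[usable[sites]] if sites.size else sites
        counts.append(int(use.size))
        if use.size >= max(min_snps, 1):
            denom = (a[use] + b[use] + c[use]).sum()
            vals.append(a[use].sum() / denom if abs(denom) > 1e-300 else np.nan)
        else:
            vals.append(np.nan)
    out["n_snps"] = counts
    out["fst_weighted"] = vals
    return out


def ld_r2(h1: np.ndarray, h2: np.ndarray) -> float:
    """Haplotype r^2 between two sites: D^2 / (p1 q1 p2 q2) over the
    jointly-called haplotypes.  NaN if either site is monomorphic there.
    """
    h1 = np.asarray(h1)
    h2 = np.asarray(h2)
    ok = (h1 >= 0) & (h2 >= 0)
    if ok.sum() < 2:
        return float("nan")
    x, y = h1[ok].astype(np.float64), h2[ok].astype(np.float64)
    p1, p2 = x.mean(), y.mean()
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        return float("nan")
    f11 = (x * y).mean()
    D = f11 - p1 * p2
    return float(D * D / (p1 * (1 - p1) * p2 * (1 - p2)))


@dataclass
class LDDecayCurve:
    """Mean r^2 by physical-distance bin, per contig and pooled."""

    bin_edges: np.ndarray  # bp, len = n_bins + 1, covers (0, max_dist]
    mean_r2: np.ndarray
    n_pairs: np.ndarray
    mode: str = "haplotype"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1],
                "bin_end": self.bin_edges[1:],
                "mean_r2": self.mean_r2,
                "n_pairs": self.n_pairs,
            }
        )


def _phase_available(gm: GenotypeMatrix) -> bool:
    called = gm.dosage >= 0
    hap_ok = (gm.haplotypes[0::2] >= 0) & (gm.haplotypes[1::2] >= 0)
    return bool(np.all(hap_ok | ~called))


def ld_decay(
    gm_group: GenotypeMatrix,
    max_dist: int = 15_000,
    maf_min: float = 0.05,
    bin_bp: int = 500,
) -> LDDecayCurve:
    """LD decay: mean pairwise r^2 in distance bins up to ``max_dist``.

    All intra-contig site pairs at distance <= max_dist with both MAFs
    >= maf_min contribute.  Haplotype r^2 when the panel is fully phased,
    dosage-correlation r^2 otherwise (mode recorded on the curve).
    """
    edges = np.arange(0, max_dist + bin_bp, bin_bp)
    edges[-1] = max(edges[-1], max_dist)
    n_bins = edges.size - 1
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)

    maf = gm_group.maf()
    keep = np.isfinite(maf) & (maf >= maf_min)
    phased = _phase_available(gm_group)
    X = (gm_group.haplotypes if phased else gm_group.dosage).astype(np.float64)
    X[X < 0] = np.nan

    for contig in pd.unique(gm_group.contig):
        on = np.flatnonzero((gm_group.contig == contig) & keep)
        pos = gm_group.pos0[on]
        for ii, i in enumerate(on):
            jmax = np.searchsorted(pos, pos[ii] + max_dist, side="right")
            for jj in range(ii + 1, jmax):
                j = on[jj]
                d = pos[jj] - pos[ii]
                if d <= 0:
                    continue
                r2 = _pair_r2(X[:, i], X[:, j])
                if np.isfinite(r2):
                    b = min(int((d - 1) // bin_bp), n_bins - 1)
                    sums[b] += r2
                    counts[b] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LDDecayCurve(
        bin_edges=edges,
        mean_r2=mean,
        n_pairs=counts,
        mode="haplotype" if phased else "dosage",
    )


def _pair_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation over jointly-observed entries.

    For 0/1 haplotype columns this equals D^2/(p1 q1 p2 q2).
    """
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 2:
        return float("nan")
    xv, yv = x[ok], y[ok]
    vx = xv.var()
    vy = yv.var()
    if vx <= 0 or vy <= 0:
        return float("nan")
    cov = ((xv - xv.mean()) * (yv - yv.mean())).mean()
    return float(cov * cov / (vx * vy))


def ld_prune(
    gm: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_max: float = 0.5,
) -> np.ndarray:
    """Greedy plink-style ``--indep-pairwise`` pruning on dosage r^2.

    Scans 50-SNP windows advancing 5 SNPs; within each window any pair
    with r^2 > ``r2_max`` loses its later-positioned member.  Returns the
    sorted indices of surviving variants; no surviving pair within any
    scanned window exceeds the threshold.
    """
    X = gm.dosage.astype(np.float64)
    X[X < 0] = np.nan
    n = gm.n_variants
    alive = np.ones(n, dtype=bool)
    start = 0
    while start < n:
        stop = min(start + window_snps, n)
        members = [i for i in range(start, stop) if alive[i]]
        changed = True
        while changed:
            changed = False
            for ai in range(len(members)):
                i = members[ai]
                if not alive[i]:
                    continue
                for aj in range(ai + 1, len(members)):
                    j = members[aj]
                    if not alive[j]:
                        continue
                    r2 = _pair_r2(X[:, i], X[:, j])
                    if np.isfinite(r2) and r2 > r2_max:
                        alive[j] = False  # later-positioned SNP removed
                        changed = True
            members = [i for i in members if alive[i]]
        if stop == n:
            break
        start += step_snps
    return np.flatnonzero(alive)


def pca(
    gm_pruned: GenotypeMatrix, n_components: int = 10
) -> Tuple[pd.DataFrame, np.ndarray]:
    """PCA of Patterson-scaled genotypes.

    Dosages are centred by 2*p_hat and divided by sqrt(p_hat*(1-p_hat));
    missing entries become 0 after centring (mean imputation).  Columns
    monomorphic in the called sample are dropped.  Returns per-sample
    coordinates on the top components and all eigenvalues (non-increasing)
    of the sample covariance of the scaled matrix.
    """
    if gm_pruned.n_samples < 2:
        raise ValueError("PCA needs >= 2 samples")
    c_ref, c_alt = gm_pruned.allele_counts()
    tot = c_ref + c_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, c_alt / np.maximum(tot, 1), np.nan)
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    G = gm_pruned.dosage[:, poly].astype(np.float64)
    p = p[poly]
    scale = np.sqrt(p * (1.0 - p))
    Z = np.where(G >= 0, (G - 2.0 * p) / scale, 0.0)

    C = Z @ Z.T / Z.shape[1]
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    k = min(n_components, evals.size)
    coords = evecs[:, :k] * np.sqrt(np.maximum(evals[:k], 0.0))
    df = pd.DataFrame(
        coords, index=gm_pruned.samples, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return df, evals
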
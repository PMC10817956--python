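"""VCF ingestion, genotype data model, and SNP/sample quality filters.

The genotype container keeps a dosage view (0/1/2, -1 = missing) alongside a
phased haplotype view (0/1, -1 = missing or unphased), per-genotype GQ/DP
when the VCF provides them, and variant coordinates.  Coordinates are
0-based half-open internally; the 1-based VCF convention is converted at
the I/O boundary and nowhere else.

The filter chain mirrors a common resequencing QC recipe: per-genotype
masking on quality (keep iff GQ > 15 and DP > 3), then site-level drops in
a fixed order (non-biallelic, missingness >= 20%, MAF <= 0.05, Hardy-
Weinberg exact-test p < 1e-7), then removal of one member of any sample
pair with relatedness > 0.9 (Yang et al. Ajk estimator, the VCFtools
``--relatedness`` default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from scipy.special import gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "PopulationMap",
    "FilterConfig",
    "FilterReport",
    "read_vcf",
    "read_popmap",
    "hwe_exact_test",
    "relatedness_matrix",
    "apply_filters",
    "split_by_population",
    "pool_populations",
]

MISSING = -1


@dataclass
class GenotypeMatrix:
    """In-memory genotype panel.

    Attributes
    ----------
    contig : array of str, per variant
    pos0 : array of int, 0-based variant positions (half-open convention)
    ref, alt : arrays of str (``alt`` holds the first ALT allele)
    dosage : (n_samples, n_variants) int8, ALT-allele count, -1 missing
    haplotypes : (2*n_samples, n_variants) int8, -1 where missing/unphased
    gq, dp : optional (n_samples, n_variants) arrays
    is_biallelic_snp : per-variant bool (multi-allelics retained but marked)
    samples : sample identifiers
    contig_lengths : contig -> length from the VCF header (may be empty)
    """

    contig: np.ndarray
    pos0: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray
    haplotypes: np.ndarray
    samples: List[str]
    is_biallelic_snp: np.ndarray
    contig_lengths: Dict[str, int] = field(default_factory=dict)
    gq: Optional[np.ndarray] = None
    dp: Optional[np.ndarray] = None

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return int(self.pos0.size)

    def take_variants(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            contig=self.contig[idx],
            pos0=self.pos0[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            dosage=self.dosage[:, idx],
            haplotypes=self.haplotypes[:, idx],
            samples=list(self.samples),
            is_biallelic_snp=self.is_biallelic_snp[idx],
            contig_lengths=dict(self.contig_lengths),
            gq=None if self.gq is None else self.gq[:, idx],
            dp=None if self.dp is None else self.dp[:, idx],
        )

    def take_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        unknown = [s for s in sample_ids if s not in pos]
        if unknown:
            raise KeyError(f"unknown samples: {unknown}")
        idx = np.array([pos[s] for s in sample_ids], dtype=np.int64)
        hap_idx = np.empty(2 * idx.size, dtype=np.int64)
        hap_idx[0::2], hap_idx[1::2] = 2 * idx, 2 * idx + 1
        return GenotypeMatrix(
            contig=self.contig,
            pos0=self.pos0,
            ref=self.ref,
            alt=self.alt,
            dosage=self.dosage[idx],
            haplotypes=self.haplotypes[hap_idx],
            samples=[self.samples[i] for i in idx],
            is_biallelic_snp=self.is_biallelic_snp,
            contig_lengths=dict(self.contig_lengths),
            gq=None if self.gq is None else self.gq[idx],
            dp=None if self.dp is None else self.dp[idx],
        )

    def allele_counts(self) -> Tuple[np.ndarray, np.ndarray]:
        """(ref_count, alt_count) of called alleles per variant, from dosage."""
        called = self.dosage >= 0
        n_called = called.sum(axis=0)
        alt = np.where(self.dosage > 0, self.dosage, 0).sum(axis=0)
        return 2 * n_called - alt, alt

    def missing_rate(self) -> np.ndarray:
        return (self.dosage < 0).mean(axis=0)

    def maf(self) -> np.ndarray:
        """Minor allele frequency over called alleles (NaN if none called)."""
        c_ref, c_alt = self.allele_counts()
        tot = c_ref + c_alt
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(tot > 0, c_alt / np.maximum(tot, 1), np.nan)
        return np.minimum(p, 1.0 - p)


@dataclass
class PopulationMap:
    """Sample → population and population → group assignments.

    ``group_order`` fixes the cross-population sign convention for the
    haplotype-based scan: a positive score means longer haplotype
    homozygosity in the first-listed group.
    """

    sample_to_pop: Dict[str, str]
    pop_to_group: Dict[str, str] = field(default_factory=dict)
    group_order: Tuple[str, str] = ("A", "B")

    def populations(self) -> List[str]:
        seen: Dict[str, None] = {}
        for p in self.sample_to_pop.values():
            seen.setdefault(p, None)
        return list(seen)

    def samples_of(self, pops: Sequence[str]) -> List[str]:
        pops = set(pops)
        return [s for s, p in self.sample_to_pop.items() if p in pops]

    def pops_of_group(self, group: str) -> List[str]:
        return [p for p, g in self.pop_to_group.items() if g == group]

    def validate_against(self, samples: Sequence[str]) -> None:
        missing = [s for s in samples if s not in self.sample_to_pop]
        if missing:
            raise ValueError(f"samples absent from population map: {missing}")


def read_popmap(path, group_order: Tuple[str, str] = None) -> PopulationMap:
    """Read a `sample<TAB>population[<TAB>group]` table."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("population map needs at least sample and population columns")
    s2p = dict(zip(df[0], df[1]))
    p2g: Dict[str, str] = {}
    if df.shape[1] >= 3:
        p2g = dict(zip(df[1], df[2]))
    if group_order is None:
        groups = list(dict.fromkeys(p2g.values())) or ["A", "B"]
        group_order = tuple(groups[:2]) if len(groups) >= 2 else (groups[0], groups[0])
    return PopulationMap(sample_to_pop=s2p, pop_to_group=p2g, group_order=group_order)


@dataclass(frozen=True)
class FilterConfig:
    """QC thresholds; ``None`` disables the corresponding filter."""

    maf_min: Optional[float] = 0.05
    gq_min: Optional[float] = 15.0
    dp_min: Optional[float] = 3.0
    max_missing: Optional[float] = 0.20
    hwe_p_min: Optional[float] = 1e-7
    biallelic_only: bool = True
    relatedness_max: Optional[float] = 0.9


@dataclass
class FilterReport:
    n_input_sites: int = 0
    n_genotypes_masked: int = 0
    dropped: Dict[str, int] = field(default_factory=dict)
    n_kept_sites: int = 0
    samples_removed: List[str] = field(default_factory=list)
    site_reasons: Optional[pd.DataFrame] = None  # contig, pos0, reason

    def to_summary_frame(self) -> pd.DataFrame:
        rows = [("input_sites", self.n_input_sites)]
        rows += [(f"dropped_{k}", v) for k, v in self.dropped.items()]
        rows += [
            ("kept_sites", self.n_kept_sites),
            ("genotypes_masked", self.n_genotypes_masked),
            ("samples_removed", len(self.samples_removed)),
        ]
        return pd.DataFrame(rows, columns=["item", "count"])


def _parse_region(region: str) -> Tuple[str, int, int]:
    """'chr1:10001-20000' (1-based inclusive) -> (chr1, 10000, 20000) half-open."""
    if ":" not in region:
        return region, 0, np.iinfo(np.int64).max
    contig, span = region.split(":", 1)
    lo, hi = span.split("-")
    return contig, int(lo) - 1, int(hi)


def read_vcf(path, region: Optional[str] = None) -> GenotypeMatrix:
    """Load a VCF into a :class:`GenotypeMatrix`.

    Multi-allelic records are retained but flagged for the biallelic
    filter.  Unphased genotypes keep their dosage but have no haplotype
    view (-1).  ``region`` is 'contig' or 'contig:start-end', 1-based
    inclusive as in VCF practice.
    """
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    n = len(samples)
    contig_lengths: Dict[str, int] = {}
    for c, ln in zip(vcf.seqnames, vcf.seqlens or []):
        contig_lengths[c] = int(ln)

    want = _parse_region(region) if region else None

    contigs, pos0s, refs, alts, bial = [], [], [], [], []
    dos_rows, hap_rows, gq_rows, dp_rows = [], [], [], []
    saw_gq = saw_dp = False
    for var in vcf:
        p0 = var.start  # cyvcf2: 0-based
        if want is not None:
            c, lo, hi = want
            if var.CHROM != c or not (lo <= p0 < hi):
                continue
        gts = var.genotypes  # [[a, b, phased], ...]
        if gts is None:
            raise ValueError(f"record without GT at {var.CHROM}:{var.POS}")
        dos = np.full(n, MISSING, dtype=np.int8)
        hap = np.full(2 * n, MISSING, dtype=np.int8)
        for i, g in enumerate(gts):
            a, b = g[0], g[1]
            phased = bool(g[2]) if len(g) > 2 else False
            if a < 0 or b < 0:
                continue
            dos[i] = (1 if a > 0 else 0) + (1 if b > 0 else 0)  # non-ref count
            if phased or a == b:  # homozygotes are trivially phased
                hap[2 * i], hap[2 * i + 1] = a, b
        contigs.append(var.CHROM)
        pos0s.append(p0)
        refs.append(var.REF)
        alts.append(var.ALT[0] if var.ALT else ".")
        bial.append(
            len(var.ALT) == 1 and len(var.REF) == 1 and len(var.ALT[0]) == 1
        )
        dos_rows.append(dos)
        hap_rows.append(hap)
        try:
            gq = var.format("GQ")
        except KeyError:
            gq = None
        try:
            dp = var.format("DP")
        except KeyError:
            dp = None
        if gq is not None:
            saw_gq = True
            gq_rows.append(np.asarray(gq, dtype=np.float32).reshape(n))
        else:
            gq_rows.append(np.full(n, np.nan, dtype=np.float32))
        if dp is not None:
            saw_dp = True
            dp_rows.append(np.asarray(dp, dtype=np.float32).reshape(n))
        else:
            dp_rows.append(np.full(n, np.nan, dtype=np.float32))

    m = len(pos0s)
    gm = GenotypeMatrix(
        contig=np.array(contigs, dtype=object),
        pos0=np.array(pos0s, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        dosage=(
            np.stack(dos_rows, axis=1) if m else np.zeros((n, 0), dtype=np.int8)
        ),
        haplotypes=(
            np.stack(hap_rows, axis=1) if m else np.zeros((2 * n, 0), dtype=np.int8)
        ),
        samples=samples,
        is_biallelic_snp=np.array(bial, dtype=bool),
        contig_lengths=contig_lengths,
        gq=np.stack(gq_rows, axis=1) if (m and saw_gq) else None,
        dp=np.stack(dp_rows, axis=1) if (m and saw_dp) else None,
    )
    if m and not saw_gq:
        logger.warning("VCF has no GQ FORMAT field; GQ filter will be a no-op")
    if m and not saw_dp:
        logger.warning("VCF has no DP FORMAT field; DP filter will be a no-op")
    return gm


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test on the heterozygote count.

    Conditional on the observed allele counts, sums the probabilities of
    every heterozygote count (same parity) whose probability does not
    exceed that of the observed configuration (Wigginton-style mid-p-free
    exact test).  Monomorphic sites return 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0

    # unnormalized probabilities over all het counts with the right parity
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    # P(n_Aa = h) ∝ n! / (hom_r! hom_c! h!) * 2^h with fixed allele counts
    hom_r = (n_rare - hets) // 2
    hom_c = n - hets - hom_r
    logp = hets * np.log(2.0) - (
        gammaln(hom_r + 1) + gammaln(hom_c + 1) + gammaln(hets + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[np.flatnonzero(hets == n_Aa)[0]]
    p = float(probs[probs <= obs * (1 + 1e-12)].sum())
    return min(p, 1.0)


def relatedness_matrix(gm: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise Yang et al. Ajk relatedness (VCFtools ``--relatedness``).

    Off-diagonal: mean over usable sites of
    ``(g_i - 2p)(g_j - 2p) / (2p(1-p))``; diagonal uses the within-sample
    form ``(g^2 - (1+2p)g + 2p^2) / (2p(1-p))``.  Sites monomorphic in the
    called sample are skipped; missing genotypes drop a site for the pairs
    involving them.
    """
    if gm.n_samples < 2:
        raise ValueError("relatedness needs at least two samples")
    G = gm.dosage.astype(np.float64)
    called = gm.dosage >= 0
    c_ref, c_alt = gm.allele_counts()
    tot = c_ref + c_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, c_alt / np.maximum(tot, 1), np.nan)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic sites")
    G = G[:, poly]
    called = called[:, poly]
    p = p[poly]
    denom = 2.0 * p * (1.0 - p)

    Z = np.where(called, (G - 2.0 * p) / np.sqrt(denom), 0.0)
    M = called.astype(np.float64)
    num = Z @ Z.T
    cnt = M @ M.T
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(cnt > 0, num / cnt, np.nan)
    # diagonal: within-individual estimator, 1 + mean per-site term
    diag_num = np.where(called, (G * G - (1.0 + 2.0 * p) * G + 2.0 * p * p) / denom, 0.0)
    dcnt = called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        np.fill_diagonal(
            A, np.where(dcnt > 0, 1.0 + diag_num.sum(axis=1) / dcnt, np.nan)
        )
    return pd.DataFrame(A, index=gm.samples, columns=gm.samples)


def _hwe_pvalues(gm: GenotypeMatrix, sites: np.ndarray) -> np.ndarray:
    out = np.ones(sites.size)
    for k, j in enumerate(sites):
        col = gm.dosage[:, j]
        n_aa = int((col == 2).sum())
        n_Aa = int((col == 1).sum())
        n_AA = int((col == 0).sum())
        if n_AA + n_Aa + n_aa >= 1:
            out[k] = hwe_exact_test(n_AA, n_Aa, n_aa)
    return out


def apply_filters(
    gm: GenotypeMatrix, fc: FilterConfig, pm: Optional[PopulationMap] = None
) -> Tuple[GenotypeMatrix, FilterReport]:
    """Apply the QC chain and return the filtered matrix plus a report.

    Stage order is fixed: genotype masking (GQ/DP) → non-biallelic →
    missingness → MAF → HWE → related-sample removal.  Thresholds follow a
    strict reading of the usual inequalities: keep iff GQ > gq_min,
    DP > dp_min, missing < max_missing, MAF > maf_min, HWE p >= hwe_p_min.
    Of a related pair the member with higher missingness is removed (ties:
    the later sample ID).
    """
    rep = FilterReport(n_input_sites=gm.n_variants)
    work = gm

    # --- genotype-level masking
    mask = np.zeros_like(work.dosage, dtype=bool)
    if fc.gq_min is not None and work.gq is not None:
        with np.errstate(invalid="ignore"):
            mask |= (work.dosage >= 0) & ~np.isnan(work.gq) & (work.gq <= fc.gq_min)
    if fc.dp_min is not None and work.dp is not None:
        with np.errstate(invalid="ignore"):
            mask |= (work.dosage >= 0) & ~np.isnan(work.dp) & (work.dp <= fc.dp_min)
    if mask.any():
        dosage = work.dosage.copy()
        haps = work.haplotypes.copy()
        dosage[mask] = MISSING
        hap_mask = np.repeat(mask, 2, axis=0)
        haps[hap_mask] = MISSING
        work = GenotypeMatrix(
            contig=work.contig,
            pos0=work.pos0,
            ref=work.ref,
            alt=work.alt,
            dosage=dosage,
            haplotypes=haps,
            samples=list(work.samples),
            is_biallelic_snp=work.is_biallelic_snp,
            contig_lengths=dict(work.contig_lengths),
            gq=work.gq,
            dp=work.dp,
        )
    rep.n_genotypes_masked = int(mask.sum())

    # --- site-level drops, fixed order
    alive = np.ones(work.n_variants, dtype=bool)
    reasons = np.full(work.n_variants, "", dtype=object)

    def drop(bad: np.ndarray, reason: str) -> None:
        bad = bad & alive
        reasons[bad] = reason
        rep.dropped[reason] = int(bad.sum())
        alive[bad] = False

    if fc.biallelic_only:
        drop(~work.is_biallelic_snp, "non_biallelic")
    else:
        rep.dropped["non_biallelic"] = 0
    if fc.max_missing is not None:
        drop(work.missing_rate() >= fc.max_missing, "missingness")
    else:
        rep.dropped["missingness"] = 0
    if fc.maf_min is not None:
        maf = work.maf()
        drop(np.isnan(maf) | (maf <= fc.maf_min), "maf")
    else:
        rep.dropped["maf"] = 0
    if fc.hwe_p_min is not None:
        cand = np.flatnonzero(alive)
        pvals = _hwe_pvalues(work, cand)
        bad = np.zeros(work.n_variants, dtype=bool)
        bad[cand[pvals < fc.hwe_p_min]] = True
        drop(bad, "hwe")
    else:
        rep.dropped["hwe"] = 0

    kept_idx = np.flatnonzero(alive)
    rep.n_kept_sites = int(kept_idx.size)
    rep.site_reasons = pd.DataFrame(
        {
            "contig": work.contig[~alive],
            "pos0": work.pos0[~alive],
            "reason": reasons[~alive],
        }
    )
    out = work.take_variants(kept_idx)

    # --- sample-level: drop one member of each highly related pair
    if fc.relatedness_max is not None and out.n_samples >= 2 and out.n_variants >= 1:
        try:
            A = relatedness_matrix(out).values
        except ValueError:
            A = None
        if A is not None:
            miss = (out.dosage < 0).mean(axis=1)
            removed: set = set()
            order = list(range(out.n_samples))
            pairs = [
                (i, j)
                for i in order
                for j in order
                if i < j and np.isfinite(A[i, j]) and A[i, j] > fc.relatedness_max
            ]
            for i, j in pairs:
                if i in removed or j in removed:
                    continue
                if miss[i] > miss[j]:
                    removed.add(i)
                elif miss[j] > miss[i]:
                    removed.add(j)
                else:
                    # tie on missingness: remove the later sample ID
                    removed.add(max(i, j, key=lambda k: out.samples[k]))
            if removed:
                rep.samples_removed = sorted(out.samples[k] for k in removed)
                keep = [s for s in out.samples if s not in rep.samples_removed]
                out = out.take_samples(keep)

    if out.n_variants == 0:
        warnings.warn("all sites removed by filtering", stacklevel=2)
    return out, rep


def split_by_population(
    gm: GenotypeMatrix, pm: PopulationMap, pops: Sequence[str]
) -> Dict[str, GenotypeMatrix]:
    """Per-population sub-matrices (same variants, population's samples)."""
    known = set(pm.sample_to_pop.values())
    for p in pops:
        if p not in known:
            raise KeyError(f"unknown population: {p}")
    present = set(gm.samples)
    return {
        p: gm.take_samples([s for s in pm.samples_of([p]) if s in present])
        for p in pops
    }


def pool_populations(
    gm: GenotypeMatrix, pm: PopulationMap, pops: Sequence[str]
) -> GenotypeMatrix:
    """Samples of the listed populations concatenated into one pooled panel."""
    known = set(pm.sample_to_pop.values())
    for p in pops:
        if p not in known:
            raise KeyError(f"unknown population: {p}")
    present = set(gm.samples)
    return gm.take_samples([s for s in pm.samples_of(pops) if s in present])
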
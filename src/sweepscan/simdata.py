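"""Forward-in-time Wright–Fisher simulator with optional selective sweeps.

Produces phased multi-population haplotype panels emulating a resequencing
study design of several village-chicken-like populations (a handful of
diploid samples each, dense biallelic SNPs on one contig), written out as a
phased VCF plus a sample→population map.

Model
-----
Discrete non-overlapping generations.  Each population holds ``Ne`` diploids
(``2*Ne`` haplotypes).  Every offspring gamete picks one parent (fitness-
weighted during a sweep), recombines the parent's two haplotypes with a
Poisson number of crossovers, and acquires Poisson-distributed new mutations
under the infinite-sites model (every mutation creates a new biallelic
site).  Populations split instantaneously from a common ancestral pool and
then drift independently, with optional symmetric migration.  The ancestral
pool is initialised at approximate mutation–drift equilibrium (site
frequencies drawn from the neutral site-frequency spectrum, sites in
linkage equilibrium), so short runs reach realistic diversity levels.

Selection is additive: genotype fitness 1, 1+s, 1+2s, implemented as
parent-sampling weights ``1 + s * dosage`` at the focal site.  If the
beneficial allele is lost while the sweep is active it is re-injected up to
a configurable budget; exhaustion is reported in the truth record, never an
exception.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SweepSpec",
    "SimulationConfig",
    "SweepRecord",
    "SimTruth",
    "simulate",
    "write_vcf",
    "degrade",
]


@dataclass(frozen=True)
class SweepSpec:
    """Planted-sweep parameters.

    ``init_freq=None`` injects a single copy at ``start_gen``; a float in
    (0, 1] seeds the allele at that frequency instead (useful for tracking
    drift of a standing allele with ``s=0``).
    """

    pop_index: int
    position_bp: int
    s: float
    start_gen: int
    init_freq: Optional[float] = None
    reinject_budget: int = 20


@dataclass(frozen=True)
class SimulationConfig:
    """Wright–Fisher run parameters.

    Defaults emulate a two-group comparison at desk scale: two populations
    of 10 diploid samples on a 1 Mb contig, with per-bp rates scaled up so
    a run yields a few thousand segregating SNPs.
    """

    seed: int
    n_pops: int = 2
    Ne: int = 100
    split_gen: int = 50
    migration_rate: float = 0.005
    L: int = 1_000_000
    mu: float = 2e-6
    rec: float = 2e-6
    sweep: Optional[SweepSpec] = None
    sample_sizes: Sequence[int] = (10, 10)
    depth_mean: float = 30.0
    gq_const: int = 60

    def __post_init__(self) -> None:
        if self.n_pops < 1:
            raise ValueError("n_pops must be >= 1")
        if len(self.sample_sizes) != self.n_pops:
            raise ValueError("sample_sizes must have one entry per population")
        for n in self.sample_sizes:
            if not (0 < n <= self.Ne):
                raise ValueError("each sample size must satisfy 0 < n <= Ne")
        if self.mu < 0 or self.rec < 0:
            raise ValueError("mu and rec must be >= 0")
        if not (0.0 <= self.migration_rate < 1.0):
            raise ValueError("migration_rate must be in [0, 1)")
        if self.sweep is not None:
            if not (0 <= self.sweep.position_bp < self.L):
                raise ValueError("sweep position must lie in [0, L)")
            if not (0 <= self.sweep.pop_index < self.n_pops):
                raise ValueError("sweep pop_index out of range")
            if self.sweep.s < 0:
                raise ValueError("selection coefficient must be >= 0")
            if self.sweep.start_gen > self.split_gen:
                raise ValueError("sweep cannot start before the population split")


@dataclass
class SweepRecord:
    """Ground truth for a planted sweep.

    ``span_start``/``span_end`` delimit the swept-haplotype footprint in
    the sampled panel of the selected population: the maximal interval
    around the focal site over which that sample is monomorphic (the
    region where a diversity trough must lie).
    """

    pop_index: int
    position_bp: int
    s: float
    final_freq: float
    lost: bool
    reinjections: int
    span_start: int = 0
    span_end: int = 0


@dataclass
class SimTruth:
    """Simulator output: sampled phased panels plus ground truth.

    ``haplotypes[p]`` has shape ``(2 * sample_sizes[p], n_sites)`` over the
    union site set; every column segregates in the union sample.  Optional
    degradation masks (per diploid genotype) are consulted by
    :func:`write_vcf`.
    """

    positions: np.ndarray  # bp, 0-based, strictly increasing
    haplotypes: list  # list of uint8 arrays, one per population
    pop_names: list
    contig: str
    L: int
    seed: int
    depth_mean: float
    gq_const: int
    sweep: Optional[SweepRecord] = None
    missing_mask: Optional[np.ndarray] = None  # (n_samples_total, n_sites) bool
    low_gq_mask: Optional[np.ndarray] = None

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    @property
    def sample_names(self) -> list:
        out = []
        for p, hap in enumerate(self.haplotypes):
            for i in range(hap.shape[0] // 2):
                out.append(f"{self.pop_names[p]}_s{i + 1}")
        return out


def _draw_positions(rng: np.random.Generator, n: int, L: int, used: set) -> np.ndarray:
    """n distinct integer positions on [0, L) not in `used` (rejection sampling)."""
    out = np.empty(n, dtype=np.int64)
    got = 0
    while got < n:
        cand = rng.integers(0, L, size=n - got)
        for c in cand:
            c = int(c)
            if c not in used:
                used.add(c)
                out[got] = c
                got += 1
    return out


def _equilibrium_pool(rng, twoN, theta, L, used_positions):
    """Ancestral haplotype pool at approximate mutation-drift equilibrium."""
    harm = float(np.sum(1.0 / np.arange(1, twoN)))
    n_sites = int(rng.poisson(theta * harm))
    if n_sites == 0:
        return np.zeros((twoN, 0), dtype=np.uint8), np.empty(0, dtype=np.int64)
    ks = np.arange(1, twoN)
    counts = rng.choice(ks, size=n_sites, p=(1.0 / ks) / harm)
    pool = np.zeros((twoN, n_sites), dtype=np.uint8)
    for j, k in enumerate(counts):
        pool[rng.permutation(twoN)[:k], j] = 1
    pos = _draw_positions(rng, n_sites, L, used_positions)
    order = np.argsort(pos)
    return pool[:, order], pos[order]


def simulate(config: SimulationConfig) -> SimTruth:
    """Run the forward simulation and sample the present-day panels.

    Deterministic given ``config`` (including its seed).  Columns that do
    not segregate in the union of the sampled haplotypes are dropped from
    the output; the sweep record reports the focal-allele frequency in the
    full sweep population at sampling time, and ``lost=True`` if the allele
    was lost after the re-injection budget ran out.
    """
    rng = np.random.default_rng(config.seed)
    Ne, twoN, L = config.Ne, 2 * config.Ne, config.L
    theta = 4.0 * Ne * config.mu * L
    used_positions: set = set()

    anc, positions = _equilibrium_pool(rng, twoN, theta, L, used_positions)
    pops = [anc.copy() for _ in range(config.n_pops)]

    sweep = config.sweep
    focal_col = -1  # column index of focal site, -1 = not present
    reinjections = 0
    sweep_lost = False
    exp_cross = config.rec * L
    exp_mut_total = config.mu * L * twoN * config.n_pops

    def inject_focal(k_copies: int) -> int:
        """Ensure a focal column exists and set k carriers in the sweep pop."""
        nonlocal positions, pops
        hits = np.flatnonzero(positions == sweep.position_bp)
        if hits.size:
            col = int(hits[0])
        else:
            used_positions.add(sweep.position_bp)
            positions = np.append(positions, sweep.position_bp)
            for p in range(config.n_pops):
                pops[p] = np.concatenate(
                    [pops[p], np.zeros((twoN, 1), dtype=np.uint8)], axis=1
                )
            order = np.argsort(positions, kind="stable")
            positions = positions[order]
            pops = [P[:, order] for P in pops]
            col = int(np.searchsorted(positions, sweep.position_bp))
        carriers = rng.permutation(twoN)[:k_copies]
        pops[sweep.pop_index][:, col] = 0
        pops[sweep.pop_index][carriers, col] = 1
        return col

    for gen in range(config.split_gen, 0, -1):
        if sweep is not None and gen == sweep.start_gen:
            k0 = 1 if sweep.init_freq is None else max(1, round(sweep.init_freq * twoN))
            focal_col = inject_focal(k0)
        selection_on = sweep is not None and gen <= sweep.start_gen and not sweep_lost

        # parent-sampling weights per population
        weights = [None] * config.n_pops
        if selection_on and focal_col >= 0:
            H = pops[sweep.pop_index]
            dosage = H[0::2, focal_col].astype(np.float64) + H[1::2, focal_col]
            w = 1.0 + sweep.s * dosage
            weights[sweep.pop_index] = w / w.sum()

        S = positions.size
        new_pops = []
        for p in range(config.n_pops):
            off = np.empty_like(pops[p])
            # migration: each gamete may take its parent from another pop
            src = np.full(twoN, p)
            if config.n_pops > 1 and config.migration_rate > 0.0:
                mig = rng.random(twoN) < config.migration_rate
                n_mig = int(mig.sum())
                if n_mig:
                    others = [q for q in range(config.n_pops) if q != p]
                    src[mig] = rng.choice(others, size=n_mig)
            for q in np.unique(src):
                sel = np.flatnonzero(src == q)
                m = sel.size
                wq = weights[q]
                if wq is None:
                    parents = rng.integers(0, Ne, size=m)
                else:
                    parents = rng.choice(Ne, size=m, p=wq)
                Hq = pops[q]
                # recombination: per-site phase = parity of crossovers to the
                # left of the site, plus a fair-coin starting haplotype
                n_cross = rng.poisson(exp_cross, size=m)
                tot_bp = int(n_cross.sum())
                phase = np.zeros((m, S), dtype=np.uint8)
                if tot_bp and S:
                    bp_pos = rng.integers(0, L, size=tot_bp)
                    owner = np.repeat(np.arange(m), n_cross)
                    site_idx = np.searchsorted(positions, bp_pos, side="left")
                    # each crossover flips the source haplotype for all sites
                    # to its right; breakpoints are sparse, so slice-XOR
                    for g, i in zip(owner, site_idx):
                        phase[g, i:] ^= 1
                phase ^= rng.integers(0, 2, size=m, dtype=np.uint8)[:, None]
                h0 = Hq[2 * parents]
                h1 = Hq[2 * parents + 1]
                off[sel] = h0 ^ ((h0 ^ h1) & phase)
            new_pops.append(off)
        pops = new_pops

        # new mutations: each creates a brand-new site on one random gamete
        n_new = int(rng.poisson(exp_mut_total)) if config.mu > 0 else 0
        if n_new:
            new_pos = _draw_positions(rng, n_new, L, used_positions)
            owner = rng.integers(0, twoN * config.n_pops, size=n_new)
            blocks_arr = [
                np.zeros((twoN, n_new), dtype=np.uint8) for _ in range(config.n_pops)
            ]
            cols = np.arange(n_new)
            for p in range(config.n_pops):
                mine = owner // twoN == p
                blocks_arr[p][owner[mine] % twoN, cols[mine]] = 1
            positions = np.concatenate([positions, new_pos])
            pops = [
                np.concatenate([pops[p], blocks_arr[p]], axis=1)
                for p in range(config.n_pops)
            ]
            if focal_col >= 0:
                focal_pos = sweep.position_bp
            order = np.argsort(positions, kind="stable")
            positions = positions[order]
            pops = [P[:, order] for P in pops]
            if focal_col >= 0:
                focal_col = int(np.searchsorted(positions, focal_pos))

        # sweep bookkeeping: re-inject the beneficial allele if it was lost
        if sweep is not None and gen <= sweep.start_gen and focal_col >= 0 and not sweep_lost:
            if pops[sweep.pop_index][:, focal_col].sum() == 0:
                if reinjections < sweep.reinject_budget:
                    reinjections += 1
                    carrier = int(rng.integers(0, twoN))
                    pops[sweep.pop_index][carrier, focal_col] = 1
                else:
                    sweep_lost = True

        # prune columns lost or fixed across all populations
        tot = np.zeros(positions.size, dtype=np.int64)
        for P in pops:
            tot += P.sum(axis=0, dtype=np.int64)
        keep = (tot > 0) & (tot < twoN * config.n_pops)
        if focal_col >= 0 and sweep is not None and not sweep_lost:
            keep[focal_col] = True  # keep focal even if momentarily fixed/lost
        if not keep.all():
            for pos_drop in positions[~keep]:
                used_positions.discard(int(pos_drop))
            positions = positions[keep]
            pops = [P[:, keep] for P in pops]
            if focal_col >= 0 and sweep is not None:
                hits = np.flatnonzero(positions == sweep.position_bp)
                focal_col = int(hits[0]) if hits.size else -1

        if config.mu == 0 and not (sweep is not None and gen > sweep.start_gen):
            # with no mutation the state is static once every site is absorbed
            # (a fixed/lost focal allele exerts no selection differential)
            tot2 = np.zeros(positions.size, dtype=np.int64)
            for P in pops:
                tot2 += P.sum(axis=0, dtype=np.int64)
            if np.all((tot2 == 0) | (tot2 == twoN * config.n_pops)):
                break

    # final focal frequency in the full sweep population
    sweep_rec = None
    if sweep is not None:
        if focal_col >= 0:
            freq = float(pops[sweep.pop_index][:, focal_col].sum()) / twoN
        else:
            freq = 0.0
        sweep_rec = SweepRecord(
            pop_index=sweep.pop_index,
            position_bp=sweep.position_bp,
            s=sweep.s,
            final_freq=freq,
            lost=bool(sweep_lost or (focal_col < 0)),
            reinjections=reinjections,
        )

    # draw present-day diploid samples
    sampled = []
    for p in range(config.n_pops):
        idx = np.sort(rng.choice(Ne, size=config.sample_sizes[p], replace=False))
        rows = np.empty(2 * idx.size, dtype=np.int64)
        rows[0::2], rows[1::2] = 2 * idx, 2 * idx + 1
        sampled.append(pops[p][rows])

    union = np.concatenate(sampled, axis=0)
    counts = union.sum(axis=0, dtype=np.int64)
    seg = (counts > 0) & (counts < union.shape[0])
    positions = positions[seg]
    sampled = [S[:, seg].copy() for S in sampled]

    if sweep_rec is not None and not sweep_rec.lost:
        # swept-haplotype footprint: monomorphic stretch of the selected
        # population's sample around the focal site
        A = sampled[sweep.pop_index]
        csum = A.sum(axis=0)
        poly_pos = positions[(csum > 0) & (csum < A.shape[0])]
        left = poly_pos[poly_pos < sweep.position_bp]
        right = poly_pos[poly_pos > sweep.position_bp]
        sweep_rec.span_start = int(left.max()) + 1 if left.size else 0
        sweep_rec.span_end = int(right.min()) if right.size else L
        sweep_rec.span_start = min(sweep_rec.span_start, sweep.position_bp)
        sweep_rec.span_end = max(sweep_rec.span_end, sweep.position_bp + 1)

    return SimTruth(
        positions=positions,
        haplotypes=sampled,
        pop_names=[f"pop{p + 1}" for p in range(config.n_pops)],
        contig="1",
        L=L,
        seed=config.seed,
        depth_mean=config.depth_mean,
        gq_const=config.gq_const,
        sweep=sweep_rec,
    )


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=sweepscan-simdata
##contig=<ID={contig},length={length}>
##INFO=<ID=NS,Number=1,Type=Integer,Description="Number of Samples With Data">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">
"""

LOW_GQ_VALUE = 10  # emitted for genotypes demoted by degrade(); below the GQ>15 filter


def write_vcf(truth: SimTruth, vcf_path, popmap_path, groups=None) -> None:
    """Write the sampled panels as a phased VCF 4.2 plus a population map TSV.

    One contig, REF=A / ALT=C at every site, phased ``a|b`` genotypes,
    per-genotype ``DP ~ Poisson(depth_mean)`` and constant GQ.  Degradation
    masks on ``truth`` (see :func:`degrade`) turn genotypes into ``./.`` or
    demote their GQ.  ``groups`` optionally maps population name → group
    label for the popmap's third column (default: the population name).

    Byte-deterministic given the truth object (DP noise is seeded from
    ``truth.seed``).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(truth.seed) % (2**31), 7]))
    samples = truth.sample_names
    n_samples = len(samples)
    dp = rng.poisson(truth.depth_mean, size=(n_samples, truth.n_sites))

    pops_per_sample = []
    for p, hap in enumerate(truth.haplotypes):
        pops_per_sample += [truth.pop_names[p]] * (hap.shape[0] // 2)

    with open(popmap_path, "w") as fh:
        for s, p in zip(samples, pops_per_sample):
            grp = (groups or {}).get(p, p)
            fh.write(f"{s}\t{p}\t{grp}\n")

    all_haps = np.concatenate(truth.haplotypes, axis=0)
    miss = truth.missing_mask
    lowgq = truth.low_gq_mask
    with open(vcf_path, "w") as fh:
        fh.write(_VCF_HEADER.format(contig=truth.contig, length=truth.L))
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for j in range(truth.n_sites):
            fields = [
                truth.contig,
                str(int(truth.positions[j]) + 1),  # VCF is 1-based
                ".",
                "A",
                "C",
                ".",
                "PASS",
                f"NS={n_samples}",
                "GT:DP:GQ",
            ]
            for i in range(n_samples):
                if miss is not None and miss[i, j]:
                    fields.append(f"./.:{dp[i, j]}:{truth.gq_const}")
                    continue
                a, b = all_haps[2 * i, j], all_haps[2 * i + 1, j]
                gq = LOW_GQ_VALUE if (lowgq is not None and lowgq[i, j]) else truth.gq_const
                fields.append(f"{a}|{b}:{dp[i, j]}:{gq}")
            fh.write("\t".join(fields) + "\n")


def degrade(truth: SimTruth, missing_rate: float, low_gq_rate: float, seed: int) -> SimTruth:
    """Return a copy of ``truth`` with random genotype degradation masks.

    Each diploid genotype independently becomes missing with probability
    ``missing_rate`` and (if not missing) has its GQ demoted below the
    quality filter with probability ``low_gq_rate``.  Deterministic given
    ``seed``; the underlying haplotypes are untouched.
    """
    if not (0.0 <= missing_rate <= 1.0 and 0.0 <= low_gq_rate <= 1.0):
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_samples = len(truth.sample_names)
    shape = (n_samples, truth.n_sites)
    miss = rng.random(shape) < missing_rate
    lowgq = (~miss) & (rng.random(shape) < low_gq_rate)
    out = dataclasses.replace(truth)
    out.haplotypes = [h.copy() for h in truth.haplotypes]
    out.missing_mask = miss
    out.low_gq_mask = lowgq
    return out
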
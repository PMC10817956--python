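# Methods

This note records the statistical conventions, the simulator model, and
the design decisions behind `sweepscan`, in the spirit of a methods
supplement. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Data model and coordinates

Genotypes live in a `GenotypeMatrix`: a dosage view (ALT-allele count
0/1/2, −1 missing) and a phased haplotype view (0/1, −1 where missing or
unphased; homozygous calls are treated as trivially phased). All internal
coordinates are 0-based half-open; the 1-based inclusive VCF convention is
converted only at the I/O boundary (`vcfio`). Windows, regions and BED
output all use the half-open convention, so book-ended intervals
`[a,b)`+`[b,c)` share no base but do merge (bedtools semantics).

## QC filter chain

Stages run in a fixed order so that reports are reproducible and the
chain is idempotent:

1. **genotype masking** — a called genotype becomes missing when
   GQ ≤ 15 or DP ≤ 3 (strict reading of "GQ > 15, DP > 3"); absent
   FORMAT fields make the corresponding mask a no-op with a warning;
2. **site drops**, each evaluated on the surviving sites:
   non-biallelic → missingness ≥ 0.20 → MAF ≤ 0.05 → HWE P < 1e−7.
   MAF and the HWE test use the union of all samples after masking, from
   called alleles only — the joint-genotyping context in which such
   filters are normally applied. The HWE test is the two-sided exact
   conditional test on the heterozygote count (all het counts of the
   observed parity, probability ≤ that of the observed configuration);
3. **sample removal** — of any pair with Yang et al. Ajk relatedness
   > 0.9 (the VCFtools `--relatedness` estimator: off-diagonal
   `mean[(g_i−2p)(g_j−2p)/(2p(1−p))]`, diagonal `1 + mean[(g²−(1+2p)g+2p²)/(2p(1−p))]`),
   the member with higher missingness is dropped; ties drop the
   later sample ID. Note the estimator's small-sample bias: with n
   samples the expectation for a duplicate pair is roughly `1 − O(1/n)`,
   so the 0.9 cut presumes a few dozen samples and MAF-filtered input
   (the chain runs it after the site filters for this reason).

The per-genotype (masking) rather than per-site (mean) application of the
GQ/DP thresholds is a choice; the alternative reading is a site-mean
filter, and the masking version is the stricter and more common one.

## Window statistics

Windows are built on a fixed grid: starts at 0, step, 2·step, … while
start < contig length, ends truncated at the contig end (20 kb / 10 kb
defaults). Windows with fewer than `min_snps = 10` scored SNPs are
excluded from standardization and from candidacy — never zero-filled.

* **π** — per site `c_ref·c_alt / C(c_ref+c_alt, 2)` on called allele
  counts; the window value divides the summed site values by the full
  window span in bp (the VCFtools `--window-pi` convention), not by the
  number of called sites. The output records this in metadata.
* **Inbreeding F** — `(O_hom − E_hom)/(L_called − E_hom)` per sample with
  the small-sample-corrected per-site expectation
  `1 − 2p(1−p)·2n/(2n−1)` (the VCFtools `--het` form).
* **Weir–Cockerham Fst** — the 1984 two-population estimator with
  variance components a (among populations), b (among individuals within
  populations), c (within individuals). Window values are the ratio of
  sums `Σa/Σ(a+b+c)` over usable sites (both populations called, site
  polymorphic overall), not a mean of per-site ratios. Sites with
  a+b+c = 0 are excluded rather than counted as zero.
* **LD** — haplotype r² (`D²/(p₁q₁p₂q₂)` over jointly-called haplotypes)
  when the panel is fully phased, dosage-correlation r² otherwise; the
  decay curve records which mode was used. Pruning follows the plink
  `--indep-pairwise 50 5 0.5` greedy scan on dosage r²; of an offending
  pair the later-positioned SNP is removed (the tie-break plink leaves
  unspecified; configurable).
* **PCA** — Patterson scaling (centre by 2p̂, divide by √(p̂(1−p̂)),
  missing → 0 after centring, i.e. mean imputation), eigendecomposition
  of the sample covariance; coordinates are eigenvector loadings scaled
  by √eigenvalue.

## Selection scans

**Pooled heterozygosity.** Major/minor orientation is decided per SNP
inside the pooled sample (major = more frequent observed allele), not
inherited from REF/ALT. `Hp` is algebraically bounded in [0, 0.5].
`ZHp` uses one genome-wide mean/sd over scored windows; fewer than two
scored windows, or zero variance, is an error rather than a silent NaN.

**EHH / iHH / XP-EHH.** EHH at extension x is the probability that two
random haplotypes are identical over the SNPs strictly between the core
and x (inclusive of x); the core's own allele does not partition, so
EHH(core) = 1 by construction. Curves truncate at the first value below
`ehh_cutoff = 0.05`, at `max_extend_bp = 1 Mb`, or at the contig end;
when the cutoff is never reached the last value is carried to the maximal
extension, so a panel of identical haplotypes integrates to the full
rectangle. iHH is the trapezoid integral of the curve on both sides of
the core, including the final sub-cutoff sample point (no interpolation
to the exact crossing — simpler, and both groups are treated alike).
Distances are physical bp; no genetic map is assumed. The scan removes
SNPs with any missing genotype first, computes raw `ln(iHH_A/iHH_B)` per
SNP, standardizes genome-wide, then averages within windows (signed and
absolute). The per-panel computation uses per-pair next/previous-mismatch
indices — O(pairs × sites) for the whole panel — and is verified in the
tests to agree exactly with the per-core class-walk definition. If every
raw score is identical (e.g. both groups are the same panel) the
standardized scores are defined as zero.

**Calling rules.** Hp: `ZHp ≤ −4` (boundary included). Fst:
`ZFst > 3.7` and empirical P < 0.01. XP-EHH: mean |XP-EHH_std| > 2.6,
empirical P < 0.01, and every scored SNP in the window sharing one raw
sign (zero scores are neutral); the common sign assigns the direction
(positive = group A). The 3.7/2.6 thresholds are the pair that defines
the candidate sets; a stricter 5/3.5 pair is sometimes used with the same
machinery and both are exposed in `ScanConfig`. Empirical P values are
rank-based upper-tail probabilities `#{x_j ≥ x_i}/N` (lower tail for Hp
reporting); tied values share the larger P. The ranking statistic for the
XP-EHH empirical P is the window's mean absolute standardized score,
matching the absolute-value threshold.

**Commonality.** Putative sweeps from the two-group comparison are
windows or regions detected by both scans. The window-level intersection
(identical grid coordinates) is computed and reported; the pipeline's
putative-sweep set additionally intersects at region level — each scan's
candidate windows are merged into regions and the interval intersections
are taken, direction from the XP-EHH side. The two statistics peak on the
same swept locus but respond to different footprints (allele-frequency
contrast vs haplotype length), so at small genome sizes their top-ranked
windows are routinely offset by one or two grid steps; region-level
intersection recovers the intended "common windows or regions" semantics
without loosening either scan's threshold. Merging follows bedtools
semantics; regions of opposite direction never merge.

## The simulator

Discrete-generation Wright–Fisher reproduction with `Ne` diploids per
population: each offspring gamete picks one parent (uniformly, or with
weight `1 + s·dosage` at the focal site while a sweep is active — the
additive fitness scheme 1, 1+s, 1+2s), recombines the parent's two
haplotypes with Poisson(rec·L) crossovers at uniform breakpoints, and
receives Poisson(mu·L) new mutations under infinite sites (every mutation
is a new position; positions are integers on [0, L) deduplicated by
rejection). Populations split instantaneously from a common ancestral
pool and then drift with optional symmetric migration (each gamete draws
its parent from another population with the migration probability).

The ancestral pool is initialised at approximate mutation–drift
equilibrium: the number of segregating sites is Poisson with mean
θ·a(2Ne) (θ = 4·Ne·mu·L, a the harmonic number), allele counts follow
the neutral 1/k spectrum, and sites start in linkage equilibrium. This
choice means short runs (tens of generations) operate on realistic
standing diversity; the cost is that LD older than the run length is
absent, so background haplotype structure reflects only the simulated
generations. Drift, fixation probabilities and heterozygosity decay are
exact WF properties and are verified against closed forms in the tests.

A sweep is injected as a single copy (or at a configurable standing
frequency) at `start_gen`; if lost while active it is re-injected up to a
budget, after which the truth record reports `lost` rather than raising.
The truth record also stores the final focal frequency and the
swept-haplotype footprint (the interval around the focal site over which
the selected population's sample is monomorphic).

Output is a phased VCF 4.2 (one contig, `a|b` genotypes, per-genotype
DP ~ Poisson(depth_mean), constant GQ) plus a `sample⇥population⇥group`
TSV; byte-identical for identical config and seed. `degrade()` adds
seeded per-genotype missingness and low-GQ masks to exercise the filter
chain.

### What the generator does and does not emulate

It reproduces the features the scans respond to: realistic SFS and
diversity levels, drift- and migration-controlled background
differentiation, recombination-limited haplotype sharing, and classic
hard-sweep signatures (diversity troughs, allele-frequency contrast,
extended haplotype homozygosity). It does not model sequencing error,
variant-calling artefacts, genotype-likelihood uncertainty, varying
per-site depth bias, demographic growth/bottlenecks, or soft sweeps.
Passing tests therefore demonstrate correctness of the statistics and the
calling logic under the modelled conditions, not robustness to upstream
calling artefacts in real data.

## Validation studies (tests and the acceptance script)

* **Calibration**: 20 neutral replicates of the default conditions — two
  populations of 10 diploids on 1 Mb, split 50 generations ago with
  migration 0.005, mu = rec = 2e-6/bp/gen (rates scaled up so a run
  yields several thousand SNPs). Checks that the mean fraction of windows
  passing the combined Fst ∧ XP-EHH call is within the nominal 1 % bound
  and that pooled empirical-P ranks are uniform (KS).
* **Sweep recovery**: 20 replicates of the same demography on 6 Mb
  (600 windows — an empirical P < 0.01 needs at least ~100 windows before
  any window can pass, and several hundred before the cut selects more
  than one), with an additive sweep s = 4 planted at the midpoint of
  population 1, starting 10 generations before sampling, re-injected on
  loss, and conditioned on a final focal frequency ≥ 0.9 (replicates are
  redrawn otherwise). Success criteria per replicate: the pooled-Hp scan
  over the selected group attains its genome minimum in a window
  overlapping the 20 kb span centred on the planted position (exact ties
  count — several fully swept windows can reach Hp = 0); the region-level
  Fst ∩ XP-EHH common set contains such a window with direction A; and
  the focal window's mean standardized XP-EHH is positive. The strong,
  recent sweep is deliberate: it is the regime the window statistics are
  designed to detect, and it keeps each replicate's runtime at desk
  scale.

Problem sizes (replicate counts, genome lengths, rates) are the package's
own study design, chosen for statistical resolution at desk scale.

## Known limitations

* The EHH machinery requires phased input; unphased calls are a hard
  error in the XP-EHH scan, not silently dropped.
* Empirical P values are resolution-limited to 1/N windows; genomes
  shorter than ~2 Mb (at the default grid) cannot produce any window
  with P < 0.01.
* The relatedness estimator is biased downward by O(1/n) in small
  samples; with fewer than ~20 samples true duplicates can fall under
  the 0.9 threshold.
* The diversity/pipeline code holds one contig's genotype block in
  memory; panels far beyond desk scale (hundreds of samples, tens of
  millions of SNPs) would need a chunked backend.
* No FDR layer is added on top of the fixed Z and empirical-P cutoffs —
  the calling rules are reproduced as they stand.
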
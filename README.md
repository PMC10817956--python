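# sweepscan

Selection-signature scanning and genetic-diversity statistics for
multi-population, phased SNP panels — the kind of data produced by
whole-genome resequencing of a few indigenous livestock or village-chicken
populations per environment — plus a forward Wright–Fisher simulator that
generates such panels with planted selective sweeps so every stage of the
pipeline can be validated against known truth.

## What it computes

Given a phased multi-sample VCF and a sample→population map, the pipeline

1. applies a standard SNP/sample QC chain (biallelic SNPs, MAF > 0.05,
   GQ > 15, DP > 3, missingness < 20 %, Hardy–Weinberg exact-test
   P ≥ 1e−7, removal of one member of any sample pair with Yang-estimator
   relatedness > 0.9);
2. builds a 20 kb sliding-window grid with a 10 kb step (windows with
   fewer than 10 SNPs are not scored) and runs three scans:
   * **pooled heterozygosity** — per window
     `Hp = 2 Σn_MAJ Σn_MIN / (Σn_MAJ + Σn_MIN)²` over the summed
     major/minor allele counts of the window's SNPs in a pooled sample,
     standardized genome-wide to `ZHp`; windows with `ZHp ≤ −4` are
     candidate sweeps (extreme diversity deficits);
   * **windowed weighted Fst** — Weir–Cockerham variance components
     per site, windowed as the ratio of sums `Σa / Σ(a+b+c)`,
     standardized to `ZFst`; candidates need `ZFst > 3.7` and empirical
     P < 0.01;
   * **XP-EHH** — per SNP, `ln(iHH_A / iHH_B)` where iHH is the
     trapezoid-integrated extended-haplotype-homozygosity decay curve;
     scores are standardized genome-wide, then averaged per window
     (signed and absolute); candidates need mean |XP-EHH_std| > 2.6,
     empirical P < 0.01, and all SNPs in the window agreeing in sign.
     A positive score means longer haplotype homozygosity in group A;
3. intersects the Fst and XP-EHH candidate sets (windows and regions),
   merges candidate windows bedtools-style (overlapping or book-ended,
   same direction), and annotates the resulting regions against a local
   BED/GFF3 gene file (overlaps plus nearby genes within a 30 kb flank).

Diversity utilities cover windowed nucleotide diversity (π, window-span
denominator), per-sample inbreeding F, pairwise windowed Fst between all
populations, LD decay curves (r² by distance bin up to 15 kb), plink-style
`--indep-pairwise 50 5 0.5` LD pruning, and PCA of Patterson-scaled
genotypes.

## Worked example

Simulate two populations (10 diploids each, 6 Mb) that split 50
generations ago with weak migration, plant a strong sweep
(s = 4, starting 10 generations before sampling) at position 3,000,000 in
population 1, and scan:

```sh
sweepscan simulate --config run.yaml --out-vcf panel.vcf \
    --out-popmap panel.popmap.tsv --out-truth-bed truth.bed
sweepscan scan-all --config run.yaml --outdir out
cat out/report.tsv
```

with `run.yaml` declaring the simulation above, `pooled: [pop1]`,
`group_a: [pop1]`, `group_b: [pop2]`, and a small gene BED. Output
(seed 7):

```
contig  start    end      source     direction  n_windows  peak_z               overlapping_genes  nearby_genes
1       2980000  3010000  hp         n/a        2          -7.091714037091249   TSHR               HSF1(26000bp,downstream)
1       3060000  3080000  hp         n/a        1          -4.263477857933703   gene_void          HSF1(18000bp,upstream)
1       2980000  3010000  fst_xpehh  A          7          4.669021872519925    TSHR               HSF1(26000bp,downstream)
```

Reading this: the pooled-heterozygosity scan found a two-window diversity
trough (`ZHp` peak −7.1) containing the planted locus (truth:
`1 3000000`), overlapping the gene placed there; the Fst ∩ XP-EHH
comparison called the same region with direction `A` — selection in
group A, which is where the sweep was planted — with peak `ZFst` 4.7. A
second, weaker Hp window is gene-void with a gene 18 kb away; the nearby
column reports flanking genes with their gap distance and strand-aware
upstream/downstream relation.

## Layout

| module | contents |
| --- | --- |
| `sweepscan.simdata` | Wright–Fisher simulator, VCF/popmap writer, degradation |
| `sweepscan.vcfio` | VCF reader, genotype container, HWE exact test, relatedness, QC filters |
| `sweepscan.popgen` | windows, π, inbreeding F, Weir–Cockerham Fst, LD r²/decay/pruning, PCA |
| `sweepscan.selscan` | Hp, EHH/iHH/XP-EHH, the three scans, calling, intersection, merging |
| `sweepscan.annotate` | BED/GFF3 gene input, overlap and nearby-gene reports |
| `sweepscan.studies` | canned calibration and sweep-recovery simulation studies |
| `sweepscan.cli` / `pipeline` | `sweepscan` subcommands and orchestration |

See `docs/methods.md` for the statistical conventions, simulator model and
design decisions.
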
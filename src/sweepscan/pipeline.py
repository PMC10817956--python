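"""End-to-end orchestration shared by the CLI subcommands.

Single-process, in-memory execution sized for desk-scale panels (a few
populations, one to a handful of contigs).  Every run writes a manifest
echoing the resolved thresholds, the seed, and input checksums so that a
rerun from the manifest reproduces the outputs byte-identically.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import popgen, selscan, vcfio
from .config import RunConfig
from .selscan import SweepRegion

logger = logging.getLogger(__name__)

__all__ = ["scan_all", "diversity", "write_manifest", "file_checksum"]


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_manifest(outdir: Path, cfg: RunConfig, inputs: Dict[str, str]) -> Path:
    manifest = {
        "inputs": {k: {"path": str(v), "sha256_16": file_checksum(v)} for k, v in inputs.items()},
        "filters": vars(cfg.filters).copy(),
        "scan": vars(cfg.scan).copy(),
        "populations": vars(cfg.populations).copy(),
    }
    path = outdir / "run_manifest.yaml"
    path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return path


def _load_filtered(cfg: RunConfig):
    gm = vcfio.read_vcf(cfg.io.vcf)
    pm = vcfio.read_popmap(cfg.io.popmap)
    pm.validate_against(gm.samples)
    if cfg.io.contig_allowlist:
        keep = np.isin(gm.contig, cfg.io.contig_allowlist)
        gm = gm.take_variants(np.flatnonzero(keep))
    gm_f, report = vcfio.apply_filters(gm, cfg.filters, pm)
    return gm_f, pm, report


def scan_all(cfg: RunConfig, outdir: Optional[Path] = None) -> Dict[str, object]:
    """Filter, window, run the Hp and Fst+XP-EHH scans, call, intersect,
    merge and (optionally) annotate.  Returns the in-memory results; writes
    TSV/BED outputs and a manifest when ``outdir`` is given.
    """
    gm_f, pm, report = _load_filtered(cfg)
    windows = popgen.make_windows(
        gm_f.contig_lengths, size=cfg.scan.window_size, step=cfg.scan.step
    )
    results: Dict[str, object] = {"filter_report": report, "windows": windows}

    pooled_pops = cfg.populations.pooled or pm.populations()
    gm_pooled = vcfio.pool_populations(gm_f, pm, pooled_pops)
    try:
        hp_tab = selscan.hp_scan(gm_pooled, windows, cfg.scan)
        hp_cands = selscan.call_candidates(hp_tab, cfg.scan, "hp")
        hp_regions = selscan.merge_regions(hp_cands, source="hp", z_column="ZHp")
    except selscan.StandardizationError as exc:
        logger.warning("Hp scan not standardizable: %s", exc)
        hp_tab, hp_cands, hp_regions = None, None, []
    results.update(hp_scan=hp_tab, hp_candidates=hp_cands, hp_regions=hp_regions)

    regions: List[SweepRegion] = list(hp_regions)
    if cfg.populations.group_a and cfg.populations.group_b:
        gm_a = vcfio.pool_populations(gm_f, pm, cfg.populations.group_a)
        gm_b = vcfio.pool_populations(gm_f, pm, cfg.populations.group_b)
        fst_tab = selscan.fst_scan(gm_a, gm_b, windows, cfg.scan)
        xp_tab = selscan.xpehh_scan(gm_a, gm_b, windows, cfg.scan)
        fst_cands = selscan.call_candidates(fst_tab, cfg.scan, "fst")
        xp_cands = selscan.call_candidates(xp_tab, cfg.scan, "xpehh")
        # window-level commonality (identical grid windows) plus the
        # region-level intersection used as the putative-sweep set
        common = selscan.intersect_candidates(fst_cands, xp_cands)
        common_regions = selscan.common_regions(fst_cands, xp_cands)
        regions += common_regions
        results.update(
            fst_scan=fst_tab,
            xpehh_scan=xp_tab,
            fst_candidates=fst_cands,
            xpehh_candidates=xp_cands,
            common_candidates=common,
            common_regions=common_regions,
        )
    results["regions"] = regions

    overlaps, nearby, genes = {}, {}, None
    if cfg.annotate.genes:
        genes = ann.read_genes(cfg.annotate.genes, cfg.annotate.format)
        overlaps = ann.overlap_genes(regions, genes)
        nearby = ann.nearby_genes(
            regions, genes, flank_bp=int(cfg.annotate.flank_kb * 1000)
        )
    results.update(gene_overlaps=overlaps, gene_nearby=nearby)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if hp_tab is not None:
            hp_tab.to_csv(outdir / "scan_hp.tsv", sep="\t", index=False)
        if "fst_scan" in results and results["fst_scan"] is not None:
            results["fst_scan"].to_csv(outdir / "scan_fst.tsv", sep="\t", index=False)
            results["xpehh_scan"].to_csv(
                outdir / "scan_xpehh.tsv", sep="\t", index=False
            )
        rframe = selscan.regions_to_frame(regions)
        rframe.to_csv(outdir / "regions.tsv", sep="\t", index=False)
        rframe[["contig", "start", "end", "source"]].to_csv(
            outdir / "regions.bed", sep="\t", header=False, index=False
        )
        ann.write_report(
            regions, overlaps, nearby, outdir / "report.tsv", outdir / "report.bed"
        )
        report.to_summary_frame().to_csv(
            outdir / "filter_summary.tsv", sep="\t", index=False
        )
        if report.site_reasons is not None:
            report.site_reasons.to_csv(
                outdir / "filter_sites.tsv", sep="\t", index=False
            )
        write_manifest(
            outdir, cfg, {"vcf": cfg.io.vcf, "popmap": cfg.io.popmap}
        )
    return results


def diversity(cfg: RunConfig, outdir: Optional[Path] = None) -> Dict[str, object]:
    """Per-population diversity outputs: windowed pi, per-sample F, pairwise
    windowed Fst summaries, LD decay per group, LD-pruned SNP list, PCA.
    """
    gm_f, pm, report = _load_filtered(cfg)
    windows = popgen.make_windows(
        gm_f.contig_lengths, size=cfg.scan.window_size, step=cfg.scan.step
    )
    pops = pm.populations()
    per_pop = vcfio.split_by_population(gm_f, pm, pops)

    pi_tables = {p: popgen.nucleotide_diversity(g, windows) for p, g in per_pop.items()}
    f_tables = {
        p: popgen.inbreeding_f(g) for p, g in per_pop.items() if g.n_samples >= 2
    }

    fst_rows = []
    for i, p1 in enumerate(pops):
        for p2 in pops[i + 1 :]:
            tab = popgen.windowed_weighted_fst(per_pop[p1], per_pop[p2], windows)
            fst_rows.append(
                {
                    "pop_a": p1,
                    "pop_b": p2,
                    "mean_weighted_fst": float(np.nanmean(tab["fst_weighted"])),
                    "n_windows": int(np.isfinite(tab["fst_weighted"]).sum()),
                }
            )
    fst_summary = pd.DataFrame(fst_rows)

    ld_curves = {}
    for p, g in per_pop.items():
        if g.n_samples < 2:
            logger.warning("population %s has < 2 samples; LD skipped", p)
            continue
        ld_curves[p] = popgen.ld_decay(g)

    kept = popgen.ld_prune(gm_f)
    coords, evals = (None, None)
    if gm_f.n_samples >= 2:
        coords, evals = popgen.pca(gm_f.take_variants(kept))

    results = {
        "filter_report": report,
        "pi": pi_tables,
        "inbreeding": f_tables,
        "fst_summary": fst_summary,
        "ld_decay": ld_curves,
        "pruned_indices": kept,
        "pca_coords": coords,
        "pca_eigenvalues": evals,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for p, tab in pi_tables.items():
            tab.to_csv(outdir / f"pi_{p}.tsv", sep="\t", index=False)
        for p, tab in f_tables.items():
            tab.to_csv(outdir / f"inbreeding_{p}.tsv", sep="\t", index=False)
        fst_summary.to_csv(outdir / "fst_pairs.tsv", sep="\t", index=False)
        for p, curve in ld_curves.items():
            curve.to_frame().to_csv(outdir / f"ld_decay_{p}.tsv", sep="\t", index=False)
        pd.Series(kept).to_csv(
            outdir / "pruned_snps.txt", index=False, header=False
        )
        if coords is not None:
            coords.to_csv(outdir / "pca_coords.tsv", sep="\t")
            pd.Series(evals).to_csv(
                outdir / "pca_eigenvalues.tsv", index=False, header=False
            )
        write_manifest(outdir, cfg, {"vcf": cfg.io.vcf, "popmap": cfg.io.popmap})
    return results
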
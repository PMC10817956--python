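"""Canned simulation studies: neutral calibration and sweep recovery.

These are the package's own validation experiments, shared by the test
suite and the acceptance script.  Each replicate simulates a two-group
design (two populations of 10 diploids), runs the full filter → window →
scan → call pipeline on the simulated panel, and reports per-replicate
summary metrics.

Study designs
-------------
*Calibration* — neutral two-population runs on a 1 Mb contig with
mutation and recombination rates scaled so a run yields a few thousand
SNPs.  Used to check that the empirical-P machinery is honest: the
fraction of windows called by the combined Fst ∧ XP-EHH rule stays within
the nominal bound, and empirical-P ranks are uniform.

*Sweep recovery* — identical demography on a 6 Mb genome (600 windows, so
the empirical P < 0.01 cut can select a handful of windows), with a
strong recent additive sweep (s = 4 starting 10 generations before
sampling) planted at the midpoint in group A, conditioned on the
beneficial allele reaching frequency ≥ 0.9.  Used to check that the
pooled-Hp trough, the Fst ∩ XP-EHH common set, and the XP-EHH sign all
recover the planted locus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import selscan
from .popgen import make_windows
from .selscan import ScanConfig
from .simdata import SimTruth, SimulationConfig, SweepSpec, simulate
from .vcfio import FilterConfig, GenotypeMatrix, apply_filters

__all__ = [
    "calibration_config",
    "sweep_recovery_config",
    "simulate_established_sweep",
    "truth_to_genotype_matrix",
    "NeutralReplicate",
    "SweepReplicate",
    "run_neutral_replicate",
    "run_sweep_replicate",
]

SWEEP_L = 6_000_000
SWEEP_POSITION = SWEEP_L // 2


def calibration_config(seed: int) -> SimulationConfig:
    """Neutral two-group conditions: 2 x 10 diploids, 1 Mb, mu = rec = 2e-6."""
    return SimulationConfig(seed=seed)


def sweep_recovery_config(seed: int) -> SimulationConfig:
    """Sweep conditions: 6 Mb, strong recent sweep (s=4) in population 1."""
    return SimulationConfig(
        seed=seed,
        L=SWEEP_L,
        mu=1.6e-6,
        rec=4e-6,
        split_gen=50,
        migration_rate=0.005,
        sweep=SweepSpec(
            pop_index=0,
            position_bp=SWEEP_POSITION,
            s=4.0,
            start_gen=10,
            reinject_budget=100,
        ),
    )


def simulate_established_sweep(
    seed: int, min_freq: float = 0.9, max_tries: int = 8
) -> SimTruth:
    """Simulate under the sweep-recovery conditions, redrawing the seed
    offset until the beneficial allele reaches ``min_freq`` (the study
    conditions consider only established sweeps)."""
    for t in range(max_tries):
        sub = (seed + t * 1_000_003) % (2**31)
        truth = simulate(sweep_recovery_config(sub))
        if truth.sweep is not None and truth.sweep.final_freq >= min_freq:
            return truth
    raise RuntimeError(f"sweep failed to establish in {max_tries} tries (seed {seed})")


def truth_to_genotype_matrix(truth: SimTruth) -> GenotypeMatrix:
    """Union GenotypeMatrix straight from truth haplotypes (no VCF round
    trip; serialization is exercised by its own tests)."""
    hap = np.concatenate(truth.haplotypes, axis=0).astype(np.int8)
    return GenotypeMatrix(
        contig=np.array([truth.contig] * truth.n_sites, dtype=object),
        pos0=truth.positions.astype(np.int64),
        ref=np.array(["A"] * truth.n_sites, dtype=object),
        alt=np.array(["C"] * truth.n_sites, dtype=object),
        dosage=(hap[0::2] + hap[1::2]).astype(np.int8),
        haplotypes=hap,
        samples=truth.sample_names,
        is_biallelic_snp=np.ones(truth.n_sites, dtype=bool),
        contig_lengths={truth.contig: truth.L},
    )


def _filtered_panels(truth: SimTruth):
    """Apply the default QC chain to the union panel and split the two
    populations back out."""
    gm_f, _ = apply_filters(truth_to_genotype_matrix(truth), FilterConfig())
    names = truth.sample_names
    n1 = truth.haplotypes[0].shape[0] // 2
    present = set(gm_f.samples)
    gm_a = gm_f.take_samples([s for s in names[:n1] if s in present])
    gm_b = gm_f.take_samples([s for s in names[n1:] if s in present])
    return gm_a, gm_b


@dataclass
class NeutralReplicate:
    n_windows_scored: int
    n_common_called: int
    emp_p_fst: np.ndarray
    emp_p_xpehh: np.ndarray

    @property
    def fraction_called(self) -> float:
        if self.n_windows_scored == 0:
            return 0.0
        return self.n_common_called / self.n_windows_scored


def run_neutral_replicate(seed: int, cfg: Optional[ScanConfig] = None) -> NeutralReplicate:
    """One neutral calibration replicate: simulate, filter, scan, call."""
    cfg = cfg or ScanConfig()
    truth = simulate(calibration_config(seed))
    gm_a, gm_b = _filtered_panels(truth)
    windows = make_windows({truth.contig: truth.L}, cfg.window_size, cfg.step)
    fst = selscan.fst_scan(gm_a, gm_b, windows, cfg)
    xp = selscan.xpehh_scan(gm_a, gm_b, windows, cfg)
    fst_c = selscan.call_candidates(fst, cfg, "fst")
    xp_c = selscan.call_candidates(xp, cfg, "xpehh")
    common = selscan.intersect_candidates(fst_c, xp_c)
    scored = int(np.isfinite(fst["ZFst"]).sum())
    return NeutralReplicate(
        n_windows_scored=scored,
        n_common_called=len(common),
        emp_p_fst=fst["emp_p_fst"].dropna().values,
        emp_p_xpehh=xp["emp_p_xpehh"].dropna().values,
    )


@dataclass
class SweepReplicate:
    final_freq: float
    hp_focal_is_min: bool
    common_has_focal_dir_a: bool
    focal_mean_xpehh_std: float
    focal_max_zfst: float


def run_sweep_replicate(seed: int, cfg: Optional[ScanConfig] = None) -> SweepReplicate:
    """One sweep-recovery replicate under the established-sweep conditions.

    The focal window set is the grid windows overlapping the 20 kb span
    centred on the planted position; ties in the genome-wide Hp minimum
    count as attaining it.
    """
    cfg = cfg or ScanConfig()
    truth = simulate_established_sweep(seed)
    gm_a, gm_b = _filtered_panels(truth)
    windows = make_windows({truth.contig: truth.L}, cfg.window_size, cfg.step)

    fst = selscan.fst_scan(gm_a, gm_b, windows, cfg)
    xp = selscan.xpehh_scan(gm_a, gm_b, windows, cfg)
    hp = selscan.hp_scan(gm_a, windows, cfg)

    fst_c = selscan.call_candidates(fst, cfg, "fst")
    xp_c = selscan.call_candidates(xp, cfg, "xpehh")
    regions = selscan.common_regions(fst_c, xp_c)

    fp = truth.sweep.position_bp
    lo, hi = fp - cfg.step, fp + cfg.step
    focal = (windows["start"] < hi) & (windows["end"] > lo)

    hp_vals = hp.loc[focal, "Hp"].values
    hp_ok = bool(
        np.any(np.isfinite(hp_vals))
        and np.nanmin(hp_vals) <= np.nanmin(hp["Hp"].values) + 1e-12
    )
    in_common = any(
        r.contig == truth.contig and r.start < hi and r.end > lo and r.direction == "A"
        for r in regions
    )
    xp_focal = xp.loc[focal, "mean_xpehh_std"].values
    return SweepReplicate(
        final_freq=truth.sweep.final_freq,
        hp_focal_is_min=hp_ok,
        common_has_focal_dir_a=bool(in_common),
        focal_mean_xpehh_std=float(np.nanmax(xp_focal)) if np.isfinite(xp_focal).any() else float("nan"),
        focal_max_zfst=float(np.nanmax(fst.loc[focal, "ZFst"].values)),
    )
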
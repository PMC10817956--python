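"""Run-configuration loading and validation (YAML).

A run configuration has nested sections; unknown keys anywhere are
rejected before any computation starts.  Every section is optional — a
subcommand validates that the sections it needs are present.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional

import yaml

from .selscan import ScanConfig
from .simdata import SimulationConfig, SweepSpec
from .vcfio import FilterConfig

__all__ = ["RunConfig", "load_config", "config_checksum"]


@dataclass
class IOConfig:
    vcf: Optional[str] = None
    popmap: Optional[str] = None
    outdir: str = "sweepscan_out"
    contig_allowlist: Optional[List[str]] = None  # e.g. autosomes only


@dataclass
class PopulationsConfig:
    pooled: Optional[List[str]] = None  # populations pooled for the Hp scan
    group_a: Optional[List[str]] = None  # first-listed group (positive XP-EHH)
    group_b: Optional[List[str]] = None


@dataclass
class AnnotateConfig:
    genes: Optional[str] = None
    format: Optional[str] = None
    flank_kb: float = 30.0


@dataclass
class RunConfig:
    io: IOConfig = field(default_factory=IOConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    populations: PopulationsConfig = field(default_factory=PopulationsConfig)
    simulate: Optional[SimulationConfig] = None
    annotate: AnnotateConfig = field(default_factory=AnnotateConfig)


def _build(cls, data: Dict[str, Any], where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown key(s) in '{where}': {sorted(unknown)}")
    return cls(**data)


def load_config(path) -> RunConfig:
    """Parse and schema-validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("configuration root must be a mapping")
    known = {"io", "filters", "scan", "populations", "simulate", "annotate"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown top-level section(s): {sorted(unknown)}")

    sim = None
    if "simulate" in raw:
        sdata = dict(raw["simulate"])
        sweep = sdata.pop("sweep", None)
        if sweep is not None:
            sweep = _build(SweepSpec, dict(sweep), "simulate.sweep")
        if "sample_sizes" in sdata:
            sdata["sample_sizes"] = tuple(sdata["sample_sizes"])
        sim = _build(SimulationConfig, {**sdata, "sweep": sweep}, "simulate")

    return RunConfig(
        io=_build(IOConfig, dict(raw.get("io", {})), "io"),
        filters=_build(FilterConfig, dict(raw.get("filters", {})), "filters"),
        scan=_build(ScanConfig, dict(raw.get("scan", {})), "scan"),
        populations=_build(
            PopulationsConfig, dict(raw.get("populations", {})), "populations"
        ),
        simulate=sim,
        annotate=_build(AnnotateConfig, dict(raw.get("annotate", {})), "annotate"),
    )


def config_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def apply_overrides(cfg: RunConfig, overrides) -> RunConfig:
    """Apply ``section.key=value`` command-line overrides (values parsed as
    YAML scalars).  Unknown sections or keys are rejected."""
    for item in overrides or ():
        if "=" not in item or "." not in item.split("=", 1)[0]:
            raise ValueError(f"override must look like section.key=value: {item!r}")
        dotted, raw_val = item.split("=", 1)
        section, key = dotted.split(".", 1)
        if not hasattr(cfg, section):
            raise ValueError(f"unknown config section: {section}")
        target = getattr(cfg, section)
        if target is None:
            raise ValueError(f"section '{section}' is absent from this config")
        if not any(f.name == key for f in dataclasses.fields(target)):
            raise ValueError(f"unknown key '{key}' in section '{section}'")
        value = yaml.safe_load(raw_val)
        cfg = dataclasses.replace(
            cfg, **{section: dataclasses.replace(target, **{key: value})}
        )
    return cfg
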
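"""Gene annotation of candidate sweep regions from local BED/GFF3 files.

All coordinates are 0-based half-open internally; GFF3's 1-based inclusive
convention is converted on read.  Overlap is any >= 1 bp intersection;
regions overlapping no gene are labelled gene-void.  "Nearby" genes within
a flank (default 30 kb) are reported with the gap distance and an
upstream/downstream label that is strand-aware when the annotation
provides strands and coordinate-based otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd

from .selscan import SweepRegion

__all__ = [
    "read_genes",
    "overlap_genes",
    "nearby_genes",
    "write_report",
]


def _parse_gff_attrs(attrs: str) -> Dict[str, str]:
    out = {}
    for chunk in attrs.strip().split(";"):
        if "=" in chunk:
            k, v = chunk.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_genes(path, fmt: Optional[str] = None) -> pd.DataFrame:
    """Load a gene set from BED (0-based half-open) or GFF3 (1-based
    inclusive, ``gene`` features only).

    Returns a frame with columns gene_id, gene_name, contig, start, end,
    strand (internal half-open coordinates).  Duplicate gene_ids are
    rejected.  Format is inferred from the suffix when not given.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = "gff3" if suffix in (".gff", ".gff3") else "bed"
    fmt = fmt.lower()

    if fmt == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if df.shape[1] < 3:
            raise ValueError("BED needs at least 3 columns")
        genes = pd.DataFrame(
            {
                "contig": df[0],
                "start": df[1].astype(int),
                "end": df[2].astype(int),
                "gene_id": df[3] if df.shape[1] > 3 else [
                    f"gene{i + 1}" for i in range(len(df))
                ],
                "strand": df[5] if df.shape[1] > 5 else ".",
            }
        )
        genes["gene_name"] = genes["gene_id"]
    elif fmt == "gff3":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            dtype=str,
            names=[
                "contig",
                "source",
                "type",
                "start",
                "end",
                "score",
                "strand",
                "phase",
                "attributes",
            ],
        )
        df = df[df["type"] == "gene"].reset_index(drop=True)
        attrs = df["attributes"].map(_parse_gff_attrs)
        genes = pd.DataFrame(
            {
                "contig": df["contig"],
                "start": df["start"].astype(int) - 1,  # to 0-based half-open
                "end": df["end"].astype(int),
                "gene_id": [
                    a.get("ID", a.get("gene_id", f"gene{i + 1}"))
                    for i, a in enumerate(attrs)
                ],
                "gene_name": [a.get("Name", a.get("ID", "")) for a in attrs],
                "strand": df["strand"].fillna("."),
            }
        )
        genes.loc[genes["gene_name"] == "", "gene_name"] = genes["gene_id"]
    else:
        raise ValueError(f"unknown gene-file format: {fmt}")

    if (genes["start"] >= genes["end"]).any():
        raise ValueError("gene with start >= end after coordinate conversion")
    if genes["gene_id"].duplicated().any():
        dups = genes.loc[genes["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene_ids: {dups}")
    return genes[["gene_id", "gene_name", "contig", "start", "end", "strand"]]


def write_genes_bed(genes: pd.DataFrame, path) -> None:
    """Write a gene set back out as 6-column BED (round-trip identity)."""
    out = genes[["contig", "start", "end", "gene_id"]].copy()
    out["score"] = 0
    out["strand"] = genes["strand"]
    out.to_csv(path, sep="\t", header=False, index=False)


def overlap_genes(
    regions: Sequence[SweepRegion], genes: pd.DataFrame
) -> Dict[int, List[str]]:
    """Region index -> gene_ids with >= 1 bp intersection (half-open)."""
    out: Dict[int, List[str]] = {}
    for k, r in enumerate(regions):
        g = genes[
            (genes["contig"] == r.contig)
            & (genes["start"] < r.end)
            & (genes["end"] > r.start)
        ]
        out[k] = sorted(g["gene_id"].tolist())
    return out


def nearby_genes(
    regions: Sequence[SweepRegion],
    genes: pd.DataFrame,
    flank_bp: int = 30_000,
) -> Dict[int, List[dict]]:
    """Non-overlapping genes within ``flank_bp`` of each region.

    Each hit records the gap distance between the nearest edges, a signed
    distance (negative = gene left of the region in coordinates), and an
    upstream/downstream label: with a stranded gene the label says on which
    side of the gene the region lies relative to the gene's 5' end; without
    strand, a gene left of the region is "upstream" by coordinate
    convention.  Book-ended genes have distance 0.
    """
    out: Dict[int, List[dict]] = {}
    for k, r in enumerate(regions):
        hits = []
        g = genes[genes["contig"] == r.contig]
        for row in g.itertuples(index=False):
            if row.start < r.end and row.end > r.start:
                continue  # overlapping genes reported elsewhere
            if row.end <= r.start:  # gene left of region
                dist = r.start - row.end
                signed = -dist
                side_left = True
            else:  # gene right of region
                dist = row.start - r.end
                signed = dist
                side_left = False
            if dist > flank_bp:
                continue
            if row.strand == "+":
                relation = "upstream" if side_left else "downstream"
            elif row.strand == "-":
                relation = "downstream" if side_left else "upstream"
            else:
                relation = "upstream" if side_left else "downstream"
            hits.append(
                {
                    "gene_id": row.gene_id,
                    "gene_name": row.gene_name,
                    "distance_bp": int(dist),
                    "signed_distance_bp": int(signed),
                    "relation": relation,
                }
            )
        hits.sort(key=lambda h: (h["distance_bp"], h["gene_id"]))
        out[k] = hits
    return out


def write_report(
    regions: Sequence[SweepRegion],
    overlaps: Dict[int, List[str]],
    nearby: Dict[int, List[dict]],
    tsv_path,
    bed_path=None,
) -> pd.DataFrame:
    """Emit the per-region candidate table (TSV, optional companion BED).

    One row per region: coordinates, source scan, direction, peak Z,
    overlapping genes (comma-joined, 'gene_void' if none) and nearby genes
    with distances.
    """
    rows = []
    for k, r in enumerate(regions):
        ov = overlaps.get(k, [])
        nb = nearby.get(k, [])
        rows.append(
            {
                "contig": r.contig,
                "start": r.start,
                "end": r.end,
                "source": r.source,
                "direction": r.direction,
                "n_windows": r.n_windows,
                "peak_z": r.peak_z,
                "overlapping_genes": ",".join(ov) if ov else "gene_void",
                "nearby_genes": ";".join(
                    f"{h['gene_id']}({h['distance_bp']}bp,{h['relation']})"
                    for h in nb
                ),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "contig",
            "start",
            "end",
            "source",
            "direction",
            "n_windows",
            "peak_z",
            "overlapping_genes",
            "nearby_genes",
        ],
    )
    df.to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        df[["contig", "start", "end", "source"]].to_csv(
            bed_path, sep="\t", header=False, index=False
        )
    return df
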
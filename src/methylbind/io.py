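"""Readers and writers for the plain-text formats the pipeline speaks.

Internal coordinates are 0-based half-open everywhere; conversion happens
only here.  The methylation call TSV uses 1-based positions (the CX-report
dialect); BED files and the gene-model TSV are 0-based half-open; catalog
BED6 stores each site center as a 1-base interval with its orientation in
column 6.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .footprint import CutSiteTrack, FootprintProfile
from .frap import FrapTrace
from .methylation import RECORD_COLUMNS, SiteCatalog

# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(path, genome: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from pyfaidx import Fasta

    with Fasta(str(path)) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


# ---------------------------------------------------------------------------
# methylation calls (1-based TSV)
# ---------------------------------------------------------------------------

def write_methylation_tsv(path, records: pd.DataFrame) -> None:
    out = records[RECORD_COLUMNS].copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)


def read_methylation_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["pos"] = df["pos"] - 1
    return df[RECORD_COLUMNS]


# ---------------------------------------------------------------------------
# gene models / gene methylation / DE tables (TSV)
# ---------------------------------------------------------------------------

def write_gene_models(path, genes: pd.DataFrame) -> None:
    genes[["gene_id", "chrom", "start", "end", "strand"]].to_csv(
        path, sep="\t", index=False
    )


def read_gene_models(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """BED3/BED6 (or BED3+count) into a frame; extra columns preserved."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names + list(df.columns[len(names):])
    return df


def write_cutsite_bed(path, track: CutSiteTrack) -> None:
    """Cut sites as BED4 (chrom, pos, pos+1, count)."""
    frame = track.to_frame()
    out = pd.DataFrame(
        {
            "chrom": frame["chrom"],
            "start": frame["pos"],
            "end": frame["pos"] + 1,
            "count": frame["count"],
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


def read_cutsite_bed(path, chrom_sizes: dict[str, int], **meta) -> CutSiteTrack:
    df = read_bed(path).rename(columns={"name": "count"})
    frame = pd.DataFrame(
        {"chrom": df["chrom"], "pos": df["start"], "count": df["count"]}
    )
    return CutSiteTrack.from_frame(frame, chrom_sizes, **meta)


def write_catalog_bed(path, catalog: SiteCatalog) -> None:
    """Catalog as BED6: center as a 1-base interval, strand in column 6."""
    s = catalog.sites
    out = pd.DataFrame(
        {
            "chrom": s["chrom"],
            "start": s["pos"],
            "end": s["pos"] + 1,
            "name": catalog.context,
            "score": 0,
            "strand": s["strand"],
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


def read_catalog_bed(path, context: str | None = None) -> SiteCatalog:
    df = read_bed(path)
    ctx = context or (str(df["name"].iloc[0]) if "name" in df and len(df) else "")
    sites = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["start"],
            "strand": df["strand"] if "strand" in df else "+",
        }
    )
    return SiteCatalog(context=ctx, sites=sites, selection={"label": ctx})


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def write_profile_tsv(path, profile: FootprintProfile) -> None:
    """Profile TSV with a one-line JSON metadata header."""
    meta = {
        "stage": profile.stage,
        "normalized": profile.normalized,
        "n_sites": profile.n_sites,
        "flank": profile.flank,
        "catalog_key": list(profile.catalog_key),
    }
    with open(path, "w") as fh:
        fh.write("#" + json.dumps(meta, sort_keys=True) + "\n")
        profile.to_frame().to_csv(fh, sep="\t", index=False)


def read_profile_tsv(path) -> FootprintProfile:
    with open(path) as fh:
        header = fh.readline()
        meta = json.loads(header.lstrip("#")) if header.startswith("#") else {}
        if not header.startswith("#"):
            fh.seek(0)
        df = pd.read_csv(fh, sep="\t")
    return FootprintProfile(
        offsets=df["offset"].to_numpy(),
        values=df["value"].to_numpy(dtype=float),
        n_sites=int(meta.get("n_sites", 0)),
        stage=str(meta.get("stage", "raw")),
        catalog_key=tuple(meta.get("catalog_key", ())),
        normalized=bool(meta.get("normalized", False)),
        flank=int(meta.get("flank", 300)),
    )


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, set]:
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(path, sets: dict[str, set], description: str = "") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


# ---------------------------------------------------------------------------
# FRAP traces
# ---------------------------------------------------------------------------

def write_frap_csv(path, trace: FrapTrace) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_prebleach={trace.n_prebleach}\n")
        pd.DataFrame(
            {
                "t": trace.times,
                "frap": trace.frap,
                "control": trace.control,
                "background": trace.background,
            }
        ).to_csv(fh, index=False)


def read_frap_csv(path) -> FrapTrace:
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            n_pre = int(first.strip().split("=", 1)[1])
            df = pd.read_csv(fh)
        else:
            n_pre = 5
            fh.seek(0)
            df = pd.read_csv(fh)
    return FrapTrace(
        times=df["t"].to_numpy(dtype=float),
        frap=df["frap"].to_numpy(dtype=float),
        control=df["control"].to_numpy(dtype=float),
        background=df["background"].to_numpy(dtype=float),
        n_prebleach=n_pre,
    )


# ---------------------------------------------------------------------------
# JSON
# ---------------------------------------------------------------------------

def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n"
    )
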
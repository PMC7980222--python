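"""Tn5 cut-site tracks and knockout-normalized footprint profiles.

A cut site is the 5' coordinate of an ATAC-seq read (or both ends of a
fragment), marking a transposase insertion point.  Around each site of a
catalog, cut sites are summed into 601 single-base bins spanning offsets
-300..+300 in the site's own orientation.  Profiles are normalized to the
mean of the outermost flank bins, averaged across biological replicates,
and compared between genotypes as per-bin natural-log ratios; the mean
ln-ratio over the central bins ("footprint depth") summarizes protection:
negative values mean the numerator genotype is depleted of insertions at
the site, i.e. a protein footprint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    DegenerateProfileError,
    EmptyCatalogError,
    IncompatibleProfilesError,
    InvalidConfigurationError,
    MalformedIntervalError,
)
from .methylation import SiteCatalog

MITOCHONDRIAL_NAMES = ("chrM", "chrMT", "MT", "M")


@dataclass
class CutSiteTrack:
    """Per-chromosome dense cut-site counts."""

    counts: dict[str, np.ndarray]
    sample_id: str | None = None
    genotype: str | None = None
    replicate: int | None = None

    @property
    def total_sites(self) -> int:
        return int(sum(int(c.sum()) for c in self.counts.values()))

    def to_frame(self) -> pd.DataFrame:
        """Nonzero positions as a (chrom, pos, count) table."""
        frames = []
        for chrom in sorted(self.counts):
            arr = self.counts[chrom]
            pos = np.nonzero(arr)[0]
            frames.append(
                pd.DataFrame({"chrom": chrom, "pos": pos, "count": arr[pos]})
            )
        if not frames:
            return pd.DataFrame(columns=["chrom", "pos", "count"])
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, chrom_sizes: dict[str, int], **meta
    ) -> "CutSiteTrack":
        counts = {c: np.zeros(n, dtype=np.int64) for c, n in chrom_sizes.items()}
        for chrom, grp in frame.groupby("chrom", observed=True):
            arr = counts[str(chrom)]
            np.add.at(arr, grp["pos"].to_numpy(), grp["count"].to_numpy())
        return cls(counts=counts, **meta)


@dataclass
class FootprintProfile:
    """601-bin cut-site profile around catalog sites.

    ``stage`` walks raw -> normalized -> averaged -> ratio; ``normalized``
    records whether flank normalization has been applied (ratios are of
    averaged normalized profiles).
    """

    offsets: np.ndarray
    values: np.ndarray
    n_sites: int
    stage: str
    catalog_key: tuple = ()
    normalized: bool = False
    flank: int = 300
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.offsets) != len(self.values):
            raise InvalidConfigurationError("offsets and values differ in length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "value": self.values})


# ---------------------------------------------------------------------------
# cut-site extraction
# ---------------------------------------------------------------------------

def _blacklist_mask(
    chrom: np.ndarray, pos: np.ndarray, blacklist: pd.DataFrame
) -> np.ndarray:
    """True where (chrom, pos) falls inside a blacklist interval."""
    bad = np.zeros(pos.size, dtype=bool)
    for bchrom, grp in blacklist.groupby("chrom", observed=True):
        sel = chrom == str(bchrom)
        if not sel.any():
            continue
        ivs = grp[["start", "end"]].sort_values("start").to_numpy()
        # merge overlapping intervals so searchsorted parity works
        merged = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        starts = np.array([m[0] for m in merged])
        ends = np.array([m[1] for m in merged])
        p = pos[sel]
        idx = np.searchsorted(starts, p, side="right") - 1
        inside = (idx >= 0) & (p < ends[np.clip(idx, 0, len(ends) - 1)])
        bad[np.nonzero(sel)[0]] = inside
    return bad


def extract_cut_sites(
    intervals: pd.DataFrame,
    chrom_sizes: dict[str, int],
    blacklist: pd.DataFrame | None = None,
    mode: str = "fragment",
    drop_chroms: tuple[str, ...] = MITOCHONDRIAL_NAMES,
    **meta,
) -> CutSiteTrack:
    """Infer Tn5 cut sites from 0-based half-open BED intervals.

    ``mode='fragment'`` yields two cut sites per interval (start and
    end-1); ``mode='read'`` yields one at the 5' end (start for '+', end-1
    for '-').  Cut sites inside blacklist intervals and intervals on
    mitochondrial chromosomes are discarded.  Mapping-quality and duplicate
    filtering are assumed done upstream for BED input; use
    :func:`cut_sites_from_bam` for alignment files.
    """
    if mode not in ("fragment", "read"):
        raise InvalidConfigurationError(f"unknown mode {mode!r}")
    df = intervals
    if (df["end"].to_numpy() <= df["start"].to_numpy()).any():
        raise MalformedIntervalError("interval with end <= start")
    keep = ~df["chrom"].isin(drop_chroms)
    df = df[keep]
    starts = df["start"].to_numpy(dtype=np.int64)
    ends = df["end"].to_numpy(dtype=np.int64)
    chroms = df["chrom"].to_numpy(dtype=object).astype(str)
    if mode == "fragment":
        pos = np.concatenate([starts, ends - 1])
        chrom = np.concatenate([chroms, chroms])
    else:
        strand = (
            df["strand"].to_numpy(dtype=object).astype(str)
            if "strand" in df.columns
            else np.full(len(df), "+")
        )
        pos = np.where(strand == "-", ends - 1, starts)
        chrom = chroms
    if blacklist is not None and len(blacklist):
        bad = _blacklist_mask(chrom, pos, blacklist)
        pos, chrom = pos[~bad], chrom[~bad]
    counts = {c: np.zeros(n, dtype=np.int64) for c, n in chrom_sizes.items()}
    for c in counts:
        sel = chrom == c
        if sel.any():
            counts[c] = np.bincount(pos[sel], minlength=chrom_sizes[c]).astype(
                np.int64
            )
    return CutSiteTrack(counts=counts, **meta)


def cut_sites_from_bam(
    path: str,
    chrom_sizes: dict[str, int] | None = None,
    blacklist: pd.DataFrame | None = None,
    mapq_min: int = 20,
    drop_chroms: tuple[str, ...] = MITOCHONDRIAL_NAMES,
    **meta,
) -> CutSiteTrack:
    """Cut sites from a BAM/SAM alignment file (5' read ends).

    Secondary/supplementary/duplicate/unmapped alignments and reads below
    ``mapq_min`` are removed.
    """
    import pysam

    rows = {"chrom": [], "start": [], "end": [], "strand": []}
    with pysam.AlignmentFile(path) as bam:
        if chrom_sizes is None:
            chrom_sizes = dict(zip(bam.references, bam.lengths))
        for read in bam:
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.is_duplicate
                or read.mapping_quality < mapq_min
            ):
                continue
            rows["chrom"].append(read.reference_name)
            rows["start"].append(read.reference_start)
            rows["end"].append(read.reference_end)
            rows["strand"].append("-" if read.is_reverse else "+")
    frame = pd.DataFrame(rows)
    if len(frame) == 0:
        return CutSiteTrack(
            counts={c: np.zeros(n, dtype=np.int64) for c, n in chrom_sizes.items()},
            **meta,
        )
    return extract_cut_sites(
        frame, chrom_sizes, blacklist=blacklist, mode="read",
        drop_chroms=drop_chroms, **meta,
    )


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def aggregate_profile(
    track: CutSiteTrack, catalog: SiteCatalog, flank: int = 300
) -> FootprintProfile:
    """Sum cut sites into single-base bins at signed offsets around sites.

    Offsets run in each site's orientation: for a minus-strand site the
    genomic offset is negated.  Sites closer than ``flank`` to a
    chromosome edge (or on chromosomes absent from the track) are skipped.
    """
    if len(catalog) == 0:
        raise EmptyCatalogError("catalog has no sites")
    width = 2 * flank + 1
    values = np.zeros(width)
    used = 0
    for chrom, grp in catalog.sites.groupby("chrom", observed=True):
        arr = track.counts.get(str(chrom))
        if arr is None:
            continue
        pos = grp["pos"].to_numpy(dtype=np.int64)
        strand = grp["strand"].to_numpy(dtype=object).astype(str)
        ok = (pos - flank >= 0) & (pos + flank < arr.size)
        pos, strand = pos[ok], strand[ok]
        if pos.size == 0:
            continue
        windows = arr[pos[:, None] + np.arange(-flank, flank + 1)[None, :]]
        minus = strand == "-"
        if minus.any():
            windows[minus] = windows[minus, ::-1]
        values += windows.sum(axis=0)
        used += pos.size
    return FootprintProfile(
        offsets=np.arange(-flank, flank + 1),
        values=values,
        n_sites=used,
        stage="raw",
        catalog_key=catalog.key,
        flank=flank,
    )


def normalize_flanks(
    profile: FootprintProfile, flank_width: int = 50, pseudocount: float = 0.0
) -> FootprintProfile:
    """Divide every bin by the mean of the outermost flank bins.

    With the default flank_width of 50, the normalization window is the
    outer 100 bases of the plot (50 per edge); pass flank_width=100 for the
    100-per-edge reading.  ``pseudocount`` is added to every bin first
    (useful for sparse toy data).
    """
    if profile.stage not in ("raw", "averaged"):
        raise IncompatibleProfilesError(
            f"cannot flank-normalize a {profile.stage!r} profile"
        )
    if profile.normalized:
        pass  # renormalization is idempotent, allowed
    if not 0 < flank_width <= len(profile.values) // 2:
        raise InvalidConfigurationError("flank_width outside (0, profile half-width]")
    vals = profile.values + pseudocount
    flank_mean = np.concatenate([vals[:flank_width], vals[-flank_width:]]).mean()
    if flank_mean <= 0:
        raise DegenerateProfileError("flank mean is zero; cannot normalize")
    return replace(
        profile,
        values=vals / flank_mean,
        stage="normalized" if profile.stage == "raw" else profile.stage,
        normalized=True,
    )


def average_replicates(profiles: list[FootprintProfile]) -> FootprintProfile:
    """Per-bin arithmetic mean across biological replicates."""
    if not profiles:
        raise IncompatibleProfilesError("no profiles to average")
    first = profiles[0]
    for p in profiles[1:]:
        if (
            p.stage != first.stage
            or p.normalized != first.normalized
            or p.catalog_key != first.catalog_key
            or len(p.values) != len(first.values)
        ):
            raise IncompatibleProfilesError(
                "profiles differ in stage, normalization or catalog"
            )
    values = np.mean([p.values for p in profiles], axis=0)
    return replace(first, values=values, stage="averaged")


def footprint_ratio(
    numerator: FootprintProfile, denominator: FootprintProfile
) -> FootprintProfile:
    """Per-bin ln(numerator / denominator) of averaged normalized profiles."""
    for p, name in ((numerator, "numerator"), (denominator, "denominator")):
        if p.stage != "averaged" or not p.normalized:
            raise IncompatibleProfilesError(
                f"{name} must be an averaged, flank-normalized profile "
                f"(got stage={p.stage!r}, normalized={p.normalized})"
            )
    if numerator.catalog_key != denominator.catalog_key:
        raise IncompatibleProfilesError("ratio requires a shared catalog")
    if (denominator.values <= 0).any():
        raise DegenerateProfileError(
            "denominator has non-positive bins; consider a pseudocount"
        )
    return replace(
        numerator,
        values=np.log(numerator.values / denominator.values),
        stage="ratio",
        normalized=False,
    )


def footprint_depth(
    ratio_profile: FootprintProfile, core_halfwidth: int = 25
) -> float:
    """Mean ln-ratio over the central |offset| <= core_halfwidth bins."""
    if ratio_profile.stage != "ratio":
        raise IncompatibleProfilesError("footprint_depth expects a ratio profile")
    if core_halfwidth > ratio_profile.flank:
        raise InvalidConfigurationError("core_halfwidth exceeds the profile flank")
    core = np.abs(ratio_profile.offsets) <= core_halfwidth
    return float(ratio_profile.values[core].mean())
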
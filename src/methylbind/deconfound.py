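"""Binned-regression deconfounding of mCG and mCAC effects on expression.

Per-gene counts of methylated CG and CAC binding sites are strongly
collinear (both scale with gene length), so a naive regression of
expression change on either motif absorbs the other's effect.  The
procedure here holds one motif nearly constant by sorting genes on it and
cutting them into consecutive bins of 500, then regresses log2 fold change
on the *other* motif within each bin by ordinary least squares.  Slopes
with 95% t-intervals per bin, plus the within-bin distribution of the
binding-site composition ratio, make up the deconfounding report.

Covariates are log10(count + 1); the pseudocount keeps zero-count genes
and is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateBinError,
    EmptyJoinError,
    InputIntegrityError,
    InsufficientGenesError,
    InvalidConfigurationError,
    UndefinedCorrelationError,
)

MOTIFS = ("mCG", "mCAC")
_COUNT_COL = {"mCG": "mcg", "mCAC": "mcac"}
_LOG_COL = {"mCG": "log_mcg", "mCAC": "log_mcac"}


def fc_col(contrast: str) -> str:
    return f"log2fc::{contrast}"


def padj_col(contrast: str) -> str:
    return f"padj::{contrast}"


def join_expression_methylation(
    tables: dict[str, pd.DataFrame],
    gene_methylation: pd.DataFrame,
    pseudocount: float = 1.0,
    zero_policy: str = "pseudocount",
) -> pd.DataFrame:
    """Join DE tables to per-gene methylation over the common gene set.

    Restricted to genes present with a non-missing log2fc in *every* table
    and in the methylation table (the genes detected in all datasets).
    Adds log10(count + pseudocount) covariates; ``zero_policy='drop'``
    removes genes with a zero count in either motif instead.
    """
    if not tables:
        raise EmptyJoinError("no DE tables supplied")
    if zero_policy not in ("pseudocount", "drop"):
        raise InvalidConfigurationError(f"unknown zero_policy {zero_policy!r}")
    if gene_methylation["gene_id"].duplicated().any():
        raise InputIntegrityError("duplicate gene_ids in methylation table")
    joined = gene_methylation[
        ["gene_id", "mcg", "mcac", "total", "mcac_ratio"]
    ].copy()
    for label, de in tables.items():
        if de["gene_id"].duplicated().any():
            raise InputIntegrityError(f"duplicate gene_ids in DE table {label!r}")
        sub = de.dropna(subset=["log2fc"])[["gene_id", "log2fc"] + (
            ["padj"] if "padj" in de.columns else []
        )]
        sub = sub.rename(
            columns={"log2fc": fc_col(label), "padj": padj_col(label)}
        )
        joined = joined.merge(sub, on="gene_id", how="inner")
    if zero_policy == "drop":
        joined = joined[(joined["mcg"] > 0) & (joined["mcac"] > 0)]
    if len(joined) == 0:
        raise EmptyJoinError("no genes shared by all tables")
    joined["log_mcg"] = np.log10(joined["mcg"] + pseudocount)
    joined["log_mcac"] = np.log10(joined["mcac"] + pseudocount)
    return joined.reset_index(drop=True)


def correlate_motifs(joined: pd.DataFrame, scale: str = "log") -> float:
    """Pearson r between the two motif covariates (log10 scale by default)."""
    if len(joined) < 3:
        raise InputIntegrityError("need at least 3 genes to correlate")
    if scale == "log":
        x, y = joined["log_mcg"], joined["log_mcac"]
    elif scale == "linear":
        x, y = joined["mcg"], joined["mcac"]
    else:
        raise InvalidConfigurationError(f"unknown scale {scale!r}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero variance in a motif covariate")
    return float(stats.pearsonr(x, y)[0])


@dataclass
class GeneBin:
    """One bin of genes sorted on the binning motif."""

    bin_index: int  # 1-based among retained bins
    gene_ids: np.ndarray
    binning_motif: str
    mean_log_binning_motif: float = np.nan
    slope: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    p_slope: float = np.nan
    n: int = 0
    ratio_values: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)


def bin_genes(
    joined: pd.DataFrame,
    binning_motif: str,
    bin_size: int = 500,
    drop_edges: bool = True,
) -> list[GeneBin]:
    """Sort genes by the binning covariate and cut into consecutive bins.

    Ties break by gene_id so assignment is independent of input order.  A
    short final chunk is kept before edge-dropping, so excluding the first
    and last bins (the high-variance edges) also removes it.
    """
    if binning_motif not in MOTIFS:
        raise InvalidConfigurationError(f"unknown motif {binning_motif!r}")
    if len(joined) == 0:
        raise EmptyJoinError("joined table is empty")
    if drop_edges and len(joined) < 3 * bin_size:
        raise InsufficientGenesError(
            f"{len(joined)} genes < 3 x bin_size={bin_size}; no interior bins"
        )
    order = joined.sort_values(
        [_LOG_COL[binning_motif], "gene_id"], kind="mergesort"
    )
    ids = order["gene_id"].to_numpy()
    chunks = [ids[i : i + bin_size] for i in range(0, len(ids), bin_size)]
    if drop_edges:
        chunks = chunks[1:-1]
    return [
        GeneBin(bin_index=i + 1, gene_ids=chunk, binning_motif=binning_motif)
        for i, chunk in enumerate(chunks)
    ]


def ols_slope_ci(
    x: np.ndarray, y: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, float, float]:
    """OLS slope, 95% t-interval and two-sided p for slope = 0."""
    n = len(x)
    res = stats.linregress(x, y)
    if n > 2 and res.stderr > 0:
        tcrit = stats.t.ppf(1 - alpha / 2, n - 2)
        lo, hi = res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr
        p = float(res.pvalue)
    else:
        lo = hi = res.slope
        p = 0.0 if n > 2 else np.nan
    return float(res.slope), float(lo), float(hi), p


def bin_slope(
    gene_bin: GeneBin,
    joined: pd.DataFrame,
    x_motif: str,
    contrast: str,
) -> GeneBin:
    """Within-bin OLS of log2fc on the non-binning motif covariate.

    Returns a filled copy of the bin: slope in log2FC units per log10
    binding-site unit, 95% CI from the t distribution with n-2 df,
    two-sided p for a zero slope, the mean of the binning covariate, and
    the per-gene composition-ratio values (mCG/total when binning on mCAC,
    mCAC/total when binning on mCG).
    """
    if x_motif not in MOTIFS:
        raise InvalidConfigurationError(f"unknown motif {x_motif!r}")
    sub = joined[joined["gene_id"].isin(gene_bin.gene_ids)]
    if len(sub) < 3:
        raise DegenerateBinError(f"bin {gene_bin.bin_index} has < 3 members")
    x = sub[_LOG_COL[x_motif]].to_numpy(dtype=float)
    y = sub[fc_col(contrast)].to_numpy(dtype=float)
    if np.std(x) == 0:
        raise DegenerateBinError(
            f"bin {gene_bin.bin_index}: no variance in {x_motif}"
        )
    slope, lo, hi, p = ols_slope_ci(x, y)
    other = "mCG" if gene_bin.binning_motif == "mCAC" else "mCAC"
    total = sub["total"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(
            total > 0, sub[_COUNT_COL[other]].to_numpy(dtype=float) / total, np.nan
        )
    return GeneBin(
        bin_index=gene_bin.bin_index,
        gene_ids=gene_bin.gene_ids,
        binning_motif=gene_bin.binning_motif,
        mean_log_binning_motif=float(
            sub[_LOG_COL[gene_bin.binning_motif]].mean()
        ),
        slope=slope,
        ci_low=lo,
        ci_high=hi,
        p_slope=p,
        n=len(sub),
        ratio_values=ratio[~np.isnan(ratio)],
    )


def unbinned_slope(
    joined: pd.DataFrame, x_motif: str, contrast: str
) -> dict[str, float]:
    """Naive whole-table regression of log2fc on one motif (the confounded
    estimate the binned procedure exists to correct)."""
    x = joined[_LOG_COL[x_motif]].to_numpy(dtype=float)
    y = joined[fc_col(contrast)].to_numpy(dtype=float)
    slope, lo, hi, p = ols_slope_ci(x, y)
    return {"slope": slope, "ci_low": lo, "ci_high": hi, "p": p, "n": len(x)}


def bins_to_frame(bins: list[GeneBin]) -> pd.DataFrame:
    rows = []
    for b in bins:
        q = (
            np.percentile(b.ratio_values, [5, 50, 95])
            if b.ratio_values.size
            else (np.nan, np.nan, np.nan)
        )
        rows.append(
            {
                "bin_index": b.bin_index,
                "n": b.n,
                "mean_log_binning_motif": b.mean_log_binning_motif,
                "slope": b.slope,
                "ci_low": b.ci_low,
                "ci_high": b.ci_high,
                "p_slope": b.p_slope,
                "ratio_p05": q[0],
                "ratio_median": q[1],
                "ratio_p95": q[2],
            }
        )
    return pd.DataFrame(rows)


def deconfound_report(
    joined: pd.DataFrame,
    contrasts: list[str],
    bin_size: int = 500,
    drop_edges: bool = True,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Per-contrast, per-binning-motif slope tables.

    For each contrast and each binning motif (mCAC bins give the mCG
    effect and vice versa), returns a frame of per-bin slope, 95% CI, p,
    mean binning covariate, and the 5th/50th/95th percentiles of the
    composition ratio in the bin.
    """
    out: dict[tuple[str, str], pd.DataFrame] = {}
    for contrast in contrasts:
        if fc_col(contrast) not in joined.columns:
            raise InputIntegrityError(f"joined table lacks contrast {contrast!r}")
        for binning_motif in MOTIFS:
            x_motif = "mCG" if binning_motif == "mCAC" else "mCAC"
            bins = bin_genes(joined, binning_motif, bin_size, drop_edges)
            fitted = [bin_slope(b, joined, x_motif, contrast) for b in bins]
            out[(contrast, binning_motif)] = bins_to_frame(fitted)
    return out
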
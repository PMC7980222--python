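"""Shared-dysregulated-gene analyses.

Significance calls at an adjusted-p threshold, multi-way overlap (Venn
region) analysis, direction concordance of shared genes between contrasts,
Mann-Whitney comparisons of gene groups on methylation metrics, and a
generic hypergeometric over-representation analysis (ORA) against
user-supplied GMT gene sets with Bonferroni and Benjamini-Hochberg
corrections.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    EmptyInputError,
    InputIntegrityError,
    InvalidConfigurationError,
)


@dataclass(frozen=True)
class SignificanceCall:
    contrast: str
    genes: frozenset
    alpha: float


def call_significant(
    de_table: pd.DataFrame, alpha: float = 0.05, contrast: str = ""
) -> SignificanceCall:
    """Genes with padj strictly below alpha; missing padj excluded."""
    if not 0.0 < alpha <= 1.0:
        raise InvalidConfigurationError(f"alpha={alpha} outside (0, 1]")
    sub = de_table.dropna(subset=["padj"])
    genes = frozenset(sub.loc[sub["padj"] < alpha, "gene_id"])
    return SignificanceCall(contrast=contrast, genes=genes, alpha=alpha)


def overlap_analysis(calls: list[SignificanceCall]) -> dict:
    """Venn-region counts and named gene lists for >= 2 significance calls.

    Regions are keyed by membership pattern strings ('110' = in the first
    two calls, not the third).  'shared' is the first call intersected with
    the union of the others; per-call exclusive sets are '<label>_only'.
    """
    if len(calls) < 2:
        raise EmptyInputError("overlap analysis needs at least 2 calls")
    labels = [c.contrast or f"call{i + 1}" for i, c in enumerate(calls)]
    sets = [c.genes for c in calls]
    union = frozenset().union(*sets)
    regions: dict[str, list] = {}
    counts: dict[str, int] = {}
    for pattern in product((1, 0), repeat=len(calls)):
        if not any(pattern):
            continue
        members = set(union)
        for bit, s in zip(pattern, sets):
            members &= s if bit else (union - s)
        key = "".join(map(str, pattern))
        regions[key] = sorted(members)
        counts[key] = len(members)
    rest_union = frozenset().union(*sets[1:])
    named = {
        "shared": sorted(sets[0] & rest_union),
        f"{labels[0]}_only": sorted(sets[0] - rest_union),
    }
    for lab, s in zip(labels[1:], sets[1:]):
        others = frozenset().union(*(t for t in sets if t is not s))
        named[f"{lab}_only"] = sorted(s - others)
    pairwise = {
        f"{labels[i]}&{labels[j]}": sorted(sets[i] & sets[j])
        for i in range(len(sets))
        for j in range(i + 1, len(sets))
    }
    return {
        "labels": labels,
        "regions": regions,
        "counts": counts,
        "union_size": len(union),
        "named": named,
        "pairwise": pairwise,
    }


def direction_concordance(
    shared_genes, table_a: pd.DataFrame, table_b: pd.DataFrame
) -> dict:
    """Fraction of shared genes changing in the same direction in both
    contrasts, plus the OLS slope/r of log2fc_b on log2fc_a.

    Genes with a log2fc of exactly zero in either table count as
    discordant and are reported separately.
    """
    shared = sorted(set(shared_genes))
    if not shared:
        raise EmptyInputError("no shared genes")
    a = table_a.set_index("gene_id")["log2fc"].reindex(shared)
    b = table_b.set_index("gene_id")["log2fc"].reindex(shared)
    if a.isna().any() or b.isna().any():
        raise InputIntegrityError("shared genes missing from a table")
    av, bv = a.to_numpy(dtype=float), b.to_numpy(dtype=float)
    nonzero = (av != 0) & (bv != 0)
    concordant = nonzero & (np.sign(av) == np.sign(bv))
    res = stats.linregress(av, bv)
    return {
        "n": len(shared),
        "n_zero": int((~nonzero).sum()),
        "fraction_concordant": float(concordant.mean()),
        "slope": float(res.slope),
        "r": float(res.rvalue),
    }


def mann_whitney(x, y) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U.

    Exact null when min(n1, n2) <= 8 and the pooled sample has no ties;
    otherwise the tie-corrected normal approximation with continuity
    correction.  Returns (U, p, method).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise EmptyInputError("empty group in Mann-Whitney test")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0)), method


def group_compare(
    groups: dict[str, np.ndarray],
    pairs: list[tuple[str, str]],
    metric: str = "",
) -> pd.DataFrame:
    """Pairwise Mann-Whitney comparisons of gene groups on one metric.

    Pairs with an empty group are skipped and recorded with a warning
    rather than failing the whole comparison.
    """
    rows = []
    for a, b in pairs:
        xa = np.asarray(groups.get(a, []), dtype=float)
        xb = np.asarray(groups.get(b, []), dtype=float)
        if xa.size == 0 or xb.size == 0:
            rows.append(
                {
                    "metric": metric, "group_a": a, "group_b": b,
                    "n_a": xa.size, "n_b": xb.size,
                    "U": np.nan, "p": np.nan, "method": "skipped:empty-group",
                }
            )
            continue
        u, p, method = mann_whitney(xa, xb)
        rows.append(
            {
                "metric": metric, "group_a": a, "group_b": b,
                "n_a": xa.size, "n_b": xb.size,
                "U": u, "p": p, "method": method,
            }
        )
    return pd.DataFrame(rows)


def ora(
    query, universe, gene_sets: dict[str, set]
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query list in each gene set.

    Each set is intersected with the universe first; the p-value is the
    upper tail P(X >= overlap) for X ~ Hypergeom(|universe|, |set|,
    |query|).  Bonferroni multiplies by the number of tested sets;
    Benjamini-Hochberg step-up gives the FDR.
    """
    query = set(query)
    universe = set(universe)
    if not query <= universe:
        raise InputIntegrityError("query genes outside the universe")
    M, n = len(universe), len(query)
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & universe
        k = len(query & members)
        K = len(members)
        p = float(stats.hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        rows.append(
            {
                "set": name,
                "universe_size": M,
                "query_size": n,
                "set_size": K,
                "overlap": k,
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        m_tests = len(out)
        out["bonferroni_p"] = np.minimum(1.0, out["p"] * m_tests)
        out["bh_fdr"] = multipletests(out["p"], method="fdr_bh")[1]
        out = out.sort_values("p", kind="mergesort").reset_index(drop=True)
    return out
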
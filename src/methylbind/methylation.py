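"""Methylation-context site catalogs.

Cytosine context classification (CG / CAC / CAT / CAG / CAA / CT / CC),
strand merging of symmetric CG evidence, threshold-filtered site catalogs,
genome-wide methylation-level distributions with whole-genome scaling, and
per-gene methylated-binding-site quantification.

All positions are 0-based reference coordinates of the cytosine on its own
strand; gene intervals are half-open [start, end).  A per-site methylation
level is m = meth_count / total_count.  Summed over a gene body, the m
values give the expected number of methyl-CpG-binding-protein binding
sites; because one protein molecule occupies a symmetric mCG/mCG pair, the
strand-level CG sum is divided by two.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CONTEXTS
from .errors import (
    BoundaryError,
    EmptyInputError,
    InputIntegrityError,
    InvalidConfigurationError,
    UndefinedEstimateError,
)

RECORD_COLUMNS = ["chrom", "pos", "strand", "context", "meth_count", "total_count"]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: Default catalog selection thresholds per context:
#: (min_meth, min_cov, exact_zero).  mCG catalogs use 100% methylation at
#: >=5x (merged strands); mCAC uses >=75% at >=5x; the rarer CA/CT/CC
#: contexts are relaxed to >=50% at >=4x; unmethylated control catalogs use
#: exactly 0% at >=10x.
DEFAULT_SELECTION: dict[str, tuple[float, int]] = {
    "CG": (1.00, 5),
    "CAC": (0.75, 5),
    "CAT": (0.50, 4),
    "CAG": (0.50, 4),
    "CAA": (0.50, 4),
    "CT": (0.50, 4),
    "CC": (0.50, 4),
}
UNMETHYLATED_MIN_COV = 10

METH_BIN_LABELS = ["0%", "1-24%", "25-49%", "50-74%", "75-99%", "100%"]


def with_m(records: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with the per-site methylation level column ``m``.

    Records with zero coverage get m = NaN; downstream selections reject
    them via their coverage threshold.
    """
    out = records.copy()
    total = out["total_count"].to_numpy(dtype=float)
    meth = out["meth_count"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(total > 0, meth / total, np.nan)
    out["m"] = m
    return out


# ---------------------------------------------------------------------------
# context classification
# ---------------------------------------------------------------------------

def classify_context(genome: dict[str, str], chrom: str, pos: int, strand: str) -> str:
    """Classify the methylation context of one cytosine.

    The next base 3' on the cytosine's own strand defines the CN
    dinucleotide; CA is refined by the following base to CAC/CAT/CAG/CAA.
    On the minus strand "next" means reference position pos-1, complemented
    (strand-forward reading).
    """
    seq = genome[chrom]
    if strand == "+":
        if seq[pos] != "C":
            raise InputIntegrityError(f"{chrom}:{pos}:+ is not a cytosine")
        if pos + 1 >= len(seq):
            raise BoundaryError(f"{chrom}:{pos}:+ lacks a downstream base")
        nxt = seq[pos + 1]
        if nxt == "A" and pos + 2 >= len(seq):
            raise BoundaryError(f"{chrom}:{pos}:+ lacks a second downstream base")
        third = seq[pos + 2] if nxt == "A" else ""
    elif strand == "-":
        if seq[pos] != "G":
            raise InputIntegrityError(f"{chrom}:{pos}:- is not a cytosine")
        if pos - 1 < 0:
            raise BoundaryError(f"{chrom}:{pos}:- lacks a downstream base")
        nxt = _COMPLEMENT[seq[pos - 1]]
        if nxt == "A" and pos - 2 < 0:
            raise BoundaryError(f"{chrom}:{pos}:- lacks a second downstream base")
        third = _COMPLEMENT[seq[pos - 2]] if nxt == "A" else ""
    else:
        raise InvalidConfigurationError(f"strand must be '+' or '-', got {strand!r}")

    if nxt == "G":
        return "CG"
    if nxt == "T":
        return "CT"
    if nxt == "C":
        return "CC"
    if nxt == "A":
        if third in ("A", "C", "G", "T"):
            return "CA" + third
        raise BoundaryError(f"ambiguous base after CA at {chrom}:{pos}:{strand}")
    raise BoundaryError(f"ambiguous base after C at {chrom}:{pos}:{strand}")


def _scan_strand(codes: np.ndarray, minus: bool) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized context scan of one strand.

    ``codes`` is the reference sequence as uint8.  Returns (positions,
    context index into CONTEXTS).  Sites whose context runs off the
    chromosome edge are skipped.
    """
    A, C, G, T = (np.uint8(ord(b)) for b in "ACGT")
    n = codes.size
    if minus:
        # cytosine on minus strand = reference G; next base = complement of
        # reference pos-1, third = complement of reference pos-2.
        pos = np.nonzero(codes == G)[0]
        pos = pos[pos >= 1]
        nxt = codes[pos - 1]
        comp = {C: G, G: C, A: T, T: A}
    else:
        pos = np.nonzero(codes == C)[0]
        pos = pos[pos <= n - 2]
        nxt = codes[pos + 1]
        comp = {b: b for b in (A, C, G, T)}

    ctx = np.full(pos.size, -1, dtype=np.int8)
    # dinucleotide contexts (complement for minus strand)
    ctx[nxt == comp[G]] = CONTEXTS.index("CG")
    ctx[nxt == comp[T]] = CONTEXTS.index("CT")
    ctx[nxt == comp[C]] = CONTEXTS.index("CC")
    ca = nxt == comp[A]
    if ca.any():
        ca_pos = pos[ca]
        if minus:
            ok = ca_pos >= 2
            third = np.zeros(ca_pos.size, dtype=np.uint8)
            third[ok] = codes[ca_pos[ok] - 2]
        else:
            ok = ca_pos <= n - 3
            third = np.zeros(ca_pos.size, dtype=np.uint8)
            third[ok] = codes[ca_pos[ok] + 2]
        sub = np.full(ca_pos.size, -1, dtype=np.int8)
        for base, name in ((C, "CAC"), (T, "CAT"), (G, "CAG"), (A, "CAA")):
            sub[ok & (third == comp[base])] = CONTEXTS.index(name)
        ctx[ca] = sub
    keep = ctx >= 0
    return pos[keep], ctx[keep]


def scan_contexts(genome: dict[str, str]) -> pd.DataFrame:
    """Classify every cytosine on both strands of the reference.

    Returns a frame (chrom, pos, strand, context) sorted by chrom, pos,
    strand; edge cytosines lacking downstream bases are omitted.
    """
    frames = []
    for chrom in sorted(genome):
        codes = np.frombuffer(genome[chrom].upper().encode("ascii"), dtype=np.uint8)
        for strand, minus in (("+", False), ("-", True)):
            pos, ctx = _scan_strand(codes, minus)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos.astype(np.int64),
                        "strand": strand,
                        "context": pd.Categorical.from_codes(
                            ctx, categories=list(CONTEXTS)
                        ).astype(str),
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "context"])
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["chrom", "pos", "strand"], kind="mergesort")
    return out.reset_index(drop=True)


def count_genome_motifs(genome: dict[str, str]) -> pd.Series:
    """Total strand-level motif occurrences per context in the reference."""
    ctx = scan_contexts(genome)["context"]
    counts = ctx.value_counts()
    return counts.reindex(list(CONTEXTS), fill_value=0)


# ---------------------------------------------------------------------------
# CG strand merging
# ---------------------------------------------------------------------------

def merge_cg_strands(records: pd.DataFrame) -> pd.DataFrame:
    """Combine plus/minus evidence of each symmetric CG dinucleotide.

    meth_count and total_count are summed; the merged record is anchored at
    the plus-strand cytosine with orientation '+'.  Records covered on a
    single strand pass through, re-anchored the same way.
    """
    if len(records) == 0:
        return records.copy()
    if not (records["context"] == "CG").all():
        raise InputIntegrityError("merge_cg_strands expects only CG records")
    anchor = records["pos"].to_numpy(dtype=np.int64).copy()
    minus = (records["strand"] == "-").to_numpy()
    anchor[minus] -= 1  # minus-strand C sits on the reference G of the CpG
    tmp = records.assign(pos=anchor)
    merged = (
        tmp.groupby(["chrom", "pos"], as_index=False, sort=True)[
            ["meth_count", "total_count"]
        ].sum()
    )
    merged["strand"] = "+"
    merged["context"] = "CG"
    return with_m(merged[RECORD_COLUMNS])


# ---------------------------------------------------------------------------
# catalogs
# ---------------------------------------------------------------------------

@dataclass
class SiteCatalog:
    """A threshold-filtered, optionally subsampled set of oriented sites."""

    context: str
    sites: pd.DataFrame  # columns chrom, pos, strand
    selection: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def key(self) -> tuple:
        """Identity used to check that profiles share a catalog."""
        return (self.context, len(self.sites), self.selection.get("label", ""))


def select_sites(
    records: pd.DataFrame,
    context: str,
    min_meth: float | None = None,
    min_cov: int | None = None,
    max_meth: float = 1.0,
    exact_zero: bool = False,
    max_n: int | None = None,
    seed: int = 0,
    label: str = "",
) -> SiteCatalog:
    """Build a site catalog for one context.

    Keeps records with total_count >= min_cov and m >= min_meth (or m == 0
    exactly when ``exact_zero``).  When more than ``max_n`` qualify, a
    uniform random subset of size max_n is drawn (seeded, sampled from the
    coordinate-sorted list so the result is independent of input order).
    CG records must be pre-merged by :func:`merge_cg_strands`.
    """
    if min_meth is None or min_cov is None:
        d_meth, d_cov = DEFAULT_SELECTION.get(context, (0.5, 4))
        if exact_zero:
            d_meth, d_cov = 0.0, UNMETHYLATED_MIN_COV
        min_meth = d_meth if min_meth is None else min_meth
        min_cov = d_cov if min_cov is None else min_cov
    if not 0.0 <= min_meth <= 1.0:
        raise InvalidConfigurationError(f"min_meth={min_meth} outside [0, 1]")
    if not 0.0 <= max_meth <= 1.0:
        raise InvalidConfigurationError(f"max_meth={max_meth} outside [0, 1]")

    sub = records[records["context"] == context]
    sub = with_m(sub)
    covered = sub["total_count"].to_numpy() >= min_cov
    m = sub["m"].to_numpy()
    if exact_zero:
        keep = covered & (m == 0.0)
    else:
        keep = covered & (m >= min_meth) & (m <= max_meth)
    sel = sub.loc[keep, ["chrom", "pos", "strand"]]
    sel = sel.drop_duplicates().sort_values(
        ["chrom", "pos", "strand"], kind="mergesort"
    )
    sel = sel.reset_index(drop=True)
    if max_n is not None and len(sel) > max_n:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(sel), size=max_n, replace=False))
        sel = sel.iloc[idx].reset_index(drop=True)
    return SiteCatalog(
        context=context,
        sites=sel,
        selection={
            "min_meth": min_meth,
            "min_cov": min_cov,
            "max_meth": max_meth,
            "exact_zero": exact_zero,
            "max_n": max_n,
            "seed": seed,
            "label": label or context,
        },
    )


# ---------------------------------------------------------------------------
# genome-wide distribution
# ---------------------------------------------------------------------------

def _meth_bin(m: np.ndarray) -> np.ndarray:
    """Assign methylation levels to the six canonical bins."""
    out = np.empty(m.size, dtype=np.int8)
    out[:] = -1
    out[m == 0.0] = 0
    out[(m > 0.0) & (m < 0.25)] = 1
    out[(m >= 0.25) & (m < 0.50)] = 2
    out[(m >= 0.50) & (m < 0.75)] = 3
    out[(m >= 0.75) & (m < 1.0)] = 4
    out[m == 1.0] = 5
    return out


def methylation_distribution(
    records: pd.DataFrame,
    genome: dict[str, str] | None = None,
    min_cov: int = 5,
    genome_motif_totals: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-motif methylation-level distribution with whole-genome scaling.

    For each context, records at >= min_cov coverage are binned into
    {0%, 1-24%, 25-49%, 50-74%, 75-99%, 100%}; fractions sum to one per
    motif.  The estimated genome-wide count per bin is the bin count times
    (total motifs in the genome / covered motifs), the standard
    coverage-scaling estimate.  Genome motif totals come either from
    scanning ``genome`` or from a precomputed ``genome_motif_totals``.
    """
    if genome_motif_totals is None:
        if genome is None:
            raise InvalidConfigurationError(
                "need either a genome or precomputed motif totals"
            )
        genome_motif_totals = count_genome_motifs(genome)
    sub = with_m(records)
    sub = sub[sub["total_count"] >= min_cov]
    rows = []
    for context in CONTEXTS:
        total_motifs = int(genome_motif_totals.get(context, 0))
        cx = sub[sub["context"] == context]
        n_cov = len(cx)
        if n_cov == 0:
            if total_motifs > 0:
                raise UndefinedEstimateError(
                    f"no {context} records at >= {min_cov}x coverage; "
                    "genome scaling undefined"
                )
            continue
        bins = _meth_bin(cx["m"].to_numpy())
        counts = np.bincount(bins[bins >= 0], minlength=6)
        scale = total_motifs / n_cov
        for i, lab in enumerate(METH_BIN_LABELS):
            rows.append(
                {
                    "context": context,
                    "bin": lab,
                    "count": int(counts[i]),
                    "fraction": counts[i] / n_cov,
                    "estimated_genome_count": counts[i] * scale,
                    "covered_motifs": n_cov,
                    "total_motifs": total_motifs,
                }
            )
    if not rows:
        raise UndefinedEstimateError("no covered records in any context")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-gene methylated binding sites
# ---------------------------------------------------------------------------

def count_gene_methylation(
    records: pd.DataFrame,
    gene_models: pd.DataFrame,
    min_cov: int = 1,
) -> pd.DataFrame:
    """Per-gene methylated-binding-site quantities.

    For each gene interval [start, end): mcg = (sum of m over strand-level
    CG cytosines inside) / 2 and mcac = sum of m over CAC cytosines inside.
    Strand-level CG records are used unmerged; halving the summed m
    reproduces the one-protein-per-symmetric-mCG/mCG convention and equals
    the merged-site mean when both strands are covered.  Records below
    ``min_cov`` coverage are ignored; genes with no covered sites get 0.
    """
    if gene_models["gene_id"].duplicated().any():
        dups = gene_models.loc[gene_models["gene_id"].duplicated(), "gene_id"]
        raise InputIntegrityError(f"duplicate gene_ids: {sorted(set(dups))[:5]}")
    if len(gene_models) == 0:
        raise EmptyInputError("no gene models supplied")

    sub = with_m(records)
    sub = sub[(sub["total_count"] >= min_cov) & sub["context"].isin(["CG", "CAC"])]

    # per-chromosome sorted positions + prefix sums of m, per context
    index: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for (chrom, context), grp in sub.groupby(["chrom", "context"], observed=True):
        pos = grp["pos"].to_numpy(dtype=np.int64)
        order = np.argsort(pos, kind="mergesort")
        pos = pos[order]
        csum = np.concatenate([[0.0], np.cumsum(grp["m"].to_numpy()[order])])
        index[(str(chrom), str(context))] = (pos, csum)

    def interval_sum(chrom: str, context: str, start: int, end: int) -> float:
        entry = index.get((chrom, context))
        if entry is None:
            return 0.0
        pos, csum = entry
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        return float(csum[hi] - csum[lo])

    rows = []
    for rec in gene_models.itertuples(index=False):
        chrom, start, end = str(rec.chrom), int(rec.start), int(rec.end)
        mcg = interval_sum(chrom, "CG", start, end) / 2.0
        mcac = interval_sum(chrom, "CAC", start, end)
        total = mcg + mcac
        rows.append(
            {
                "gene_id": rec.gene_id,
                "mcg": mcg,
                "mcac": mcac,
                "total": total,
                "mcac_ratio": mcac / total if total > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)
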
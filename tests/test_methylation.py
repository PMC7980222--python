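"""Context classification, CG merging, catalogs, distributions, gene counts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylbind import (
    classify_context,
    count_gene_methylation,
    merge_cg_strands,
    methylation_distribution,
    scan_contexts,
    select_sites,
)
from methylbind.errors import (
    BoundaryError,
    InputIntegrityError,
    InvalidConfigurationError,
    UndefinedEstimateError,
)
from methylbind.methylation import count_genome_motifs, with_m

from conftest import make_records


@pytest.mark.parametrize(
    "seq,pos,strand,expected",
    [
        ("ACGT", 1, "+", "CG"),
        ("ACACT", 1, "+", "CAC"),
        ("ACATT", 1, "+", "CAT"),
        ("ACAGT", 1, "+", "CAG"),
        ("ACAAT", 1, "+", "CAA"),
        ("ACTT", 1, "+", "CT"),
        ("ACCT", 1, "+", "CC"),
        # minus-strand C at a reference G; next base read strand-forward
        ("ACG", 2, "-", "CG"),          # complement of C at pos 1 is G
        ("AGTG", 3, "-", "CAC"),        # next=comp(T)=A, third=comp(G)=C
        ("TAG", 2, "-", "CT"),          # next = comp(A) = T
    ],
)
def test_classify_context_examples(seq, pos, strand, expected):
    assert classify_context({"c": seq}, "c", pos, strand) == expected


def test_classify_context_edges():
    with pytest.raises(BoundaryError):
        classify_context({"c": "AC"}, "c", 1, "+")  # no downstream base
    with pytest.raises(BoundaryError):
        classify_context({"c": "ACA"}, "c", 1, "+")  # CA needs a third base
    with pytest.raises(BoundaryError):
        classify_context({"c": "G"}, "c", 0, "-")
    with pytest.raises(InputIntegrityError):
        classify_context({"c": "ACGT"}, "c", 0, "+")  # A is not a cytosine


def test_scan_contexts_matches_scalar_classifier(small_genome):
    """Every scanned site agrees with the per-site classifier, and every
    classifiable cytosine appears exactly once per strand."""
    scanned = scan_contexts(small_genome)
    assert not scanned.duplicated(["chrom", "pos", "strand"]).any()
    rng = np.random.default_rng(0)
    sample = scanned.sample(n=200, random_state=7)
    for rec in sample.itertuples():
        assert (
            classify_context(small_genome, rec.chrom, rec.pos, rec.strand)
            == rec.context
        )
    # completeness: count cytosines with sufficient downstream bases on chr1
    seq = small_genome["chr1"]
    n_plus = sum(
        1
        for i in range(len(seq) - 1)
        if seq[i] == "C" and not (seq[i + 1] == "A" and i + 2 >= len(seq))
    )
    assert (
        (scanned["chrom"] == "chr1") & (scanned["strand"] == "+")
    ).sum() == n_plus


@pytest.mark.parametrize(
    "plus,minus,expected_m",
    [((3, 4), (2, 2), 5 / 6), ((4, 4), (4, 4), 1.0)],
)
def test_merge_cg_strands_combines_paired_evidence(plus, minus, expected_m):
    records = make_records(
        [
            ("chr1", 10, "+", "CG", *plus),
            ("chr1", 11, "-", "CG", *minus),
        ]
    )
    merged = merge_cg_strands(records)
    assert len(merged) == 1
    row = merged.iloc[0]
    assert (row.pos, row.strand) == (10, "+")
    assert row.meth_count == plus[0] + minus[0]
    assert row.total_count == plus[1] + minus[1]
    assert row.m == pytest.approx(expected_m, abs=1e-12)


def test_merge_cg_strands_unpaired_passthrough():
    merged = merge_cg_strands(make_records([("chr1", 10, "+", "CG", 5, 5)]))
    assert len(merged) == 1
    assert merged.iloc[0].pos == 10 and merged.iloc[0].total_count == 5
    # a minus-only record re-anchors to the plus-strand C of its dinucleotide
    merged = merge_cg_strands(make_records([("chr1", 11, "-", "CG", 5, 5)]))
    assert merged.iloc[0].pos == 10 and merged.iloc[0].strand == "+"


@given(
    counts=st.lists(
        st.tuples(st.integers(0, 30), st.integers(0, 30)).map(
            lambda t: (min(t), max(t))
        ),
        min_size=1,
        max_size=20,
    )
)
@settings(deadline=None, max_examples=50)
def test_merge_cg_conserves_read_counts(counts):
    """Summed meth/total counts are invariant under strand merging."""
    rows = []
    for i, (meth, total) in enumerate(counts):
        strand = "+" if i % 2 == 0 else "-"
        pos = (i // 4) * 2 + (1 if strand == "-" else 0)
        rows.append(("chr1", pos, strand, "CG", meth, total))
    records = make_records(rows)
    merged = merge_cg_strands(records)
    assert merged["meth_count"].sum() == records["meth_count"].sum()
    assert merged["total_count"].sum() == records["total_count"].sum()


def test_select_sites_thresholds():
    records = make_records(
        [
            ("chr1", 5, "+", "CAC", 4, 5),   # m=0.8, cov 5 -> kept
            ("chr1", 9, "+", "CAC", 3, 5),   # m=0.6 -> rejected
            ("chr1", 13, "+", "CAC", 4, 4),  # m=1.0 cov 4 -> below min_cov
        ]
    )
    cat = select_sites(records, "CAC", min_meth=0.75, min_cov=5)
    assert list(cat.sites["pos"]) == [5]
    with pytest.raises(InvalidConfigurationError):
        select_sites(records, "CAC", min_meth=1.5, min_cov=5)


def test_select_sites_exact_zero_and_subsampling():
    rows = [("chr1", 2 * i, "+", "CG", 0, 12) for i in range(10)]
    records = make_records(rows)
    cat = select_sites(records, "CG", exact_zero=True, min_meth=0.0, min_cov=10,
                       max_n=5, seed=11)
    cat2 = select_sites(records, "CG", exact_zero=True, min_meth=0.0, min_cov=10,
                        max_n=5, seed=11)
    assert len(cat) == 5
    assert cat.sites.equals(cat2.sites)
    # subsampling is independent of input row order
    cat3 = select_sites(
        records.iloc[::-1], "CG", exact_zero=True, min_meth=0.0,
        min_cov=10, max_n=5, seed=11,
    )
    assert cat.sites.equals(cat3.sites)


def test_catalog_members_verify_thresholds(small_records):
    """Catalog is a subset of records and every member re-passes its
    recorded thresholds; tightening thresholds never grows the catalog."""
    records = small_records
    cat = select_sites(records, "CAC", min_meth=0.75, min_cov=5)
    sub = with_m(records)
    merged_keys = set(
        map(tuple, sub[["chrom", "pos", "strand"]].itertuples(index=False))
    )
    for site in cat.sites.itertuples(index=False):
        assert tuple(site) in merged_keys
    lookup = sub.set_index(["chrom", "pos", "strand"])
    picked = lookup.loc[list(cat.sites.itertuples(index=False, name=None))]
    assert (picked["total_count"] >= 5).all()
    assert (picked["m"] >= 0.75).all()
    for mm, cc in [(0.8, 5), (0.75, 8), (0.9, 10)]:
        tighter = select_sites(records, "CAC", min_meth=mm, min_cov=cc)
        assert len(tighter) <= len(cat)


def test_methylation_distribution_bins_and_scaling():
    records = make_records(
        [
            ("chr1", 0, "+", "CG", 5, 5),
            ("chr1", 2, "+", "CG", 6, 6),
            ("chr1", 4, "+", "CG", 3, 6),
        ]
    )
    totals = pd.Series({"CG": 6})
    dist = methylation_distribution(
        records, min_cov=5, genome_motif_totals=totals
    )
    by_bin = dist.set_index("bin")
    assert by_bin.loc["100%", "fraction"] == pytest.approx(2 / 3)
    assert by_bin.loc["50-74%", "fraction"] == pytest.approx(1 / 3)
    assert dist["fraction"].sum() == pytest.approx(1.0)
    # 2 sites in the 100% bin, 3 covered of 6 genomic motifs -> 2 * (6/3) = 4
    assert by_bin.loc["100%", "estimated_genome_count"] == pytest.approx(4.0)


def test_methylation_distribution_no_covered_sites_errors():
    records = make_records([("chr1", 0, "+", "CG", 1, 2)])
    with pytest.raises(UndefinedEstimateError):
        methylation_distribution(
            records, min_cov=5, genome_motif_totals=pd.Series({"CG": 10})
        )


def test_count_genome_motifs_partition(small_genome):
    """Every classifiable cytosine lands in exactly one context."""
    totals = count_genome_motifs(small_genome)
    assert totals.sum() == len(scan_contexts(small_genome))
    assert (totals > 0).all()


def test_count_gene_methylation_halves_cg():
    # two fully methylated symmetric CGs = 4 strand-cytosines with m=1
    records = make_records(
        [
            ("chr1", 10, "+", "CG", 5, 5),
            ("chr1", 11, "-", "CG", 5, 5),
            ("chr1", 20, "+", "CG", 7, 7),
            ("chr1", 21, "-", "CG", 4, 4),
        ]
    )
    genes = pd.DataFrame(
        [("gA", "chr1", 0, 100, "+")],
        columns=["gene_id", "chrom", "start", "end", "strand"],
    )
    out = count_gene_methylation(records, genes)
    assert out.iloc[0].mcg == pytest.approx(2.0)

    cac = make_records(
        [
            ("chr1", 30, "+", "CAC", 2, 4),
            ("chr1", 40, "+", "CAC", 1, 4),
            ("chr1", 50, "-", "CAC", 1, 4),
        ]
    )
    out = count_gene_methylation(cac, genes)
    assert out.iloc[0].mcac == pytest.approx(1.0)
    assert out.iloc[0].mcg == 0.0

    empty = count_gene_methylation(records, genes.assign(start=500, end=600))
    assert empty.iloc[0].mcg == 0.0 and empty.iloc[0].mcac == 0.0


def test_count_gene_methylation_rejects_duplicate_ids():
    genes = pd.DataFrame(
        [("gA", "chr1", 0, 50, "+"), ("gA", "chr1", 40, 90, "+")],
        columns=["gene_id", "chrom", "start", "end", "strand"],
    )
    with pytest.raises(InputIntegrityError):
        count_gene_methylation(make_records([]), genes)


def brute_force_gene_counts(records, genes, min_cov=1):
    rows = []
    for g in genes.itertuples(index=False):
        mcg = mcac = 0.0
        for r in records.itertuples(index=False):
            if (
                r.chrom == g.chrom
                and g.start <= r.pos < g.end
                and r.total_count >= min_cov
            ):
                m = r.meth_count / r.total_count
                if r.context == "CG":
                    mcg += m
                elif r.context == "CAC":
                    mcac += m
        rows.append({"gene_id": g.gene_id, "mcg": mcg / 2.0, "mcac": mcac})
    return pd.DataFrame(rows)


def test_count_gene_methylation_matches_brute_force(small_records, small_genome):
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(12)],
            "chrom": ["chr1"] * 6 + ["chr2"] * 6,
            "start": [i * 4000 for i in range(6)] * 2,
            "end": [i * 4000 + 2500 for i in range(6)] * 2,
            "strand": ["+", "-"] * 6,
        }
    )
    sub = small_records[small_records["pos"] < 30_000].head(1000)
    fast = count_gene_methylation(sub, genes)
    slow = brute_force_gene_counts(sub, genes)
    assert np.allclose(fast["mcg"], slow["mcg"], atol=1e-12)
    assert np.allclose(fast["mcac"], slow["mcac"], atol=1e-12)
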
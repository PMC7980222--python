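"""Cut-site extraction and footprint profile arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylbind import (
    CutSiteTrack,
    aggregate_profile,
    average_replicates,
    cut_sites_from_bam,
    extract_cut_sites,
    footprint_depth,
    footprint_ratio,
    normalize_flanks,
)
from methylbind.errors import (
    DegenerateProfileError,
    EmptyCatalogError,
    IncompatibleProfilesError,
    InvalidConfigurationError,
    MalformedIntervalError,
)
from methylbind.footprint import FootprintProfile
from methylbind.methylation import SiteCatalog


def make_catalog(sites, context="CG"):
    return SiteCatalog(
        context=context,
        sites=pd.DataFrame(sites, columns=["chrom", "pos", "strand"]),
    )


def make_track(chrom_size, cuts, chrom="chr1"):
    arr = np.zeros(chrom_size, dtype=np.int64)
    for pos, n in cuts:
        arr[pos] += n
    return CutSiteTrack(counts={chrom: arr})


SIZES = {"chr1": 1000}


class TestExtractCutSites:
    def test_fragment_mode_yields_both_ends(self):
        frags = pd.DataFrame([("chr1", 100, 150)], columns=["chrom", "start", "end"])
        track = extract_cut_sites(frags, SIZES, mode="fragment")
        assert track.counts["chr1"][100] == 1
        assert track.counts["chr1"][149] == 1
        assert track.total_sites == 2

    def test_read_mode_uses_five_prime_end(self):
        reads = pd.DataFrame(
            [("chr1", 100, 150, "+"), ("chr1", 200, 260, "-")],
            columns=["chrom", "start", "end", "strand"],
        )
        track = extract_cut_sites(reads, SIZES, mode="read")
        assert track.counts["chr1"][100] == 1
        assert track.counts["chr1"][259] == 1
        assert track.total_sites == 2

    def test_blacklist_and_mitochondria_filtered(self):
        frags = pd.DataFrame(
            [("chr1", 120, 140), ("chrM", 10, 30)],
            columns=["chrom", "start", "end"],
        )
        blacklist = pd.DataFrame(
            [("chr1", 110, 130)], columns=["chrom", "start", "end"]
        )
        track = extract_cut_sites(frags, SIZES, blacklist=blacklist)
        # cut at 120 blacklisted, cut at 139 kept; chrM dropped entirely
        assert track.total_sites == 1
        assert track.counts["chr1"][139] == 1

    def test_malformed_interval_raises(self):
        bad = pd.DataFrame([("chr1", 150, 150)], columns=["chrom", "start", "end"])
        with pytest.raises(MalformedIntervalError):
            extract_cut_sites(bad, SIZES)


def test_cut_sites_from_sam_applies_mapq_filter(tmp_path):
    sam = tmp_path / "toy.sam"
    sam.write_text(
        "@HD\tVN:1.6\tSO:coordinate\n"
        "@SQ\tSN:chr1\tLN:1000\n"
        "r1\t0\tchr1\t101\t60\t10M\t*\t0\t0\tAAAAAAAAAA\t*\n"   # + read, MAPQ 60
        "r2\t16\tchr1\t201\t60\t10M\t*\t0\t0\tAAAAAAAAAA\t*\n"  # - read
        "r3\t0\tchr1\t301\t5\t10M\t*\t0\t0\tAAAAAAAAAA\t*\n"    # low MAPQ
    )
    track = cut_sites_from_bam(str(sam))
    assert track.counts["chr1"][100] == 1   # SAM is 1-based
    assert track.counts["chr1"][209] == 1   # 5' end of the reverse read
    assert track.total_sites == 2


class TestAggregateProfile:
    def test_plus_site_offsets(self):
        track = make_track(1000, [(500, 3), (480, 1)])
        prof = aggregate_profile(track, make_catalog([("chr1", 500, "+")]))
        assert prof.values[prof.offsets == 0] == 3
        assert prof.values[prof.offsets == -20] == 1
        assert prof.values.sum() == 4

    def test_minus_site_negates_offset(self):
        track = make_track(1000, [(510, 1)])
        prof = aggregate_profile(track, make_catalog([("chr1", 500, "-")]))
        assert prof.values[prof.offsets == -10] == 1

    def test_empty_catalog_raises(self):
        with pytest.raises(EmptyCatalogError):
            aggregate_profile(make_track(1000, []), make_catalog([]))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        cuts = [(int(p), 1) for p in rng.integers(0, 5000, size=400)]
        sites = [
            ("chr1", int(p), "+" if rng.random() < 0.5 else "-")
            for p in rng.integers(300, 4700, size=25)
        ]
        track = make_track(5000, cuts)
        prof = aggregate_profile(track, make_catalog(sites))
        expected = np.zeros(601)
        n_pairs = 0
        for chrom, center, strand in sites:
            for pos, n in cuts:
                d = pos - center
                if strand == "-":
                    d = -d
                if -300 <= d <= 300:
                    expected[d + 300] += n
                    n_pairs += n
        assert np.array_equal(prof.values, expected)
        # conservation: total bin mass equals the number of (site, cut) pairs
        assert prof.values.sum() == n_pairs

    def test_strand_reversal_mirrors_profile(self):
        rng = np.random.default_rng(3)
        cuts = [(int(p), 1) for p in rng.integers(0, 3000, size=200)]
        sites = [("chr1", int(p), "+") for p in rng.integers(300, 2700, size=10)]
        flipped = [(c, p, "-") for c, p, _ in sites]
        track = make_track(3000, cuts)
        fwd = aggregate_profile(track, make_catalog(sites))
        rev = aggregate_profile(track, make_catalog(flipped))
        assert np.array_equal(rev.values, fwd.values[::-1])


class TestNormalizeAndAverage:
    def test_constant_profile_normalizes_to_one(self):
        prof = FootprintProfile(
            offsets=np.arange(-300, 301), values=np.full(601, 7.0),
            n_sites=10, stage="raw",
        )
        out = normalize_flanks(prof)
        assert np.allclose(out.values, 1.0)
        flank = np.concatenate([out.values[:50], out.values[-50:]])
        assert abs(flank.mean() - 1.0) < 1e-9

    def test_center_scaled_against_flanks(self):
        values = np.full(601, 2.0)
        values[100:501] = 1.0
        prof = FootprintProfile(
            offsets=np.arange(-300, 301), values=values, n_sites=5, stage="raw"
        )
        out = normalize_flanks(prof)
        assert out.values[300] == pytest.approx(0.5)
        assert out.values[0] == pytest.approx(1.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_normalization_is_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        prof = FootprintProfile(
            offsets=np.arange(-300, 301),
            values=rng.uniform(0.1, 5.0, size=601),
            n_sites=3,
            stage="raw",
        )
        once = normalize_flanks(prof)
        flank = np.concatenate([once.values[:50], once.values[-50:]])
        assert abs(flank.mean() - 1.0) < 1e-9
        twice = normalize_flanks(once.__class__(**{**once.__dict__, "stage": "raw"}))
        assert np.allclose(once.values, twice.values)

    def test_zero_flank_raises(self):
        prof = FootprintProfile(
            offsets=np.arange(-300, 301), values=np.zeros(601),
            n_sites=1, stage="raw",
        )
        with pytest.raises(DegenerateProfileError):
            normalize_flanks(prof)

    def test_average_replicates(self):
        mk = lambda v: FootprintProfile(
            offsets=np.arange(-300, 301), values=np.full(601, v),
            n_sites=4, stage="normalized", normalized=True, catalog_key=("CG", 4, "x"),
        )
        assert np.allclose(average_replicates([mk(0.4)]).values, 0.4)
        avg = average_replicates([mk(0.4), mk(0.6)])
        assert np.allclose(avg.values, 0.5)
        assert avg.stage == "averaged"
        bad = mk(0.4)
        bad.catalog_key = ("CAC", 9, "y")
        with pytest.raises(IncompatibleProfilesError):
            average_replicates([mk(0.4), bad])


class TestRatioAndDepth:
    @staticmethod
    def averaged(values):
        return FootprintProfile(
            offsets=np.arange(-300, 301), values=values, n_sites=2,
            stage="averaged", normalized=True, catalog_key=("CG", 2, "x"),
        )

    def test_identical_inputs_give_zero(self):
        v = np.random.default_rng(1).uniform(0.5, 2.0, 601)
        ratio = footprint_ratio(self.averaged(v), self.averaged(v.copy()))
        assert np.allclose(ratio.values, 0.0)

    def test_log_scaling_and_antisymmetry(self):
        den = self.averaged(np.full(601, 1.0))
        num_vals = np.full(601, 1.0)
        num_vals[300] = np.exp(-0.5)
        num = self.averaged(num_vals)
        ratio = footprint_ratio(num, den)
        assert ratio.values[300] == pytest.approx(-0.5)
        flipped = footprint_ratio(den, num)
        assert np.allclose(flipped.values, -ratio.values)

    def test_zero_denominator_raises(self):
        num = self.averaged(np.full(601, 1.0))
        den_vals = np.full(601, 1.0)
        den_vals[10] = 0.0
        with pytest.raises(DegenerateProfileError):
            footprint_ratio(num, self.averaged(den_vals))

    def test_footprint_depth(self):
        vals = np.zeros(601)
        assert footprint_depth(self.averaged(vals).__class__(
            offsets=np.arange(-300, 301), values=vals, n_sites=2, stage="ratio",
        )) == 0.0
        vals = np.zeros(601)
        vals[np.abs(np.arange(-300, 301)) <= 25] = -0.4
        prof = FootprintProfile(
            offsets=np.arange(-300, 301), values=vals, n_sites=2, stage="ratio"
        )
        assert footprint_depth(prof) == pytest.approx(-0.4)
        with pytest.raises(InvalidConfigurationError):
            footprint_depth(prof, core_halfwidth=400)
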
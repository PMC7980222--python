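"""End-to-end study workflows at the package's reference conditions.

These functions wire the modules together under the default synthetic-data
conditions (documented in docs/methods.md) and return the summary numbers
the test suite asserts on: planted-footprint recovery against the knockout
null, deconfounding of collinear mCG/mCAC effects, statistical calibration
of the binned slopes, shared-gene concordance, and FRAP half-life
recovery.
"""

from __future__ import annotations

import numpy as np

from . import deconfound, footprint, frap, methylation, shared, simulate
from .config import SimulationConfig


def _seed(seed: int, offset: int) -> int:
    return (int(seed) * 1_000_003 + offset) % (2**31)


# ---------------------------------------------------------------------------
# footprint recovery
# ---------------------------------------------------------------------------

def _genotype_profile(tracks, catalog, flank=300, edge=50):
    profiles = [
        footprint.normalize_flanks(
            footprint.aggregate_profile(t, catalog, flank=flank), flank_width=edge
        )
        for t in tracks
    ]
    return footprint.average_replicates(profiles)


def run_footprint_study(
    seed: int = 0,
    n_sites: int = 10_000,
    library_size: int = 2_000_000,
    n_replicates: int = 3,
    depth: float = 0.5,
    halfwidth: int = 25,
    genome_length: int = 6_000_000,
    n_null: int = 5,
) -> dict:
    """Planted-footprint recovery at the reference conditions.

    Simulates a genome plus bisulfite calls, builds mCG (100%, >=5x,
    merged), mCAC (>=75%, >=5x) and unmethylated-CG (0%, >=10x) catalogs of
    ``n_sites`` sites, plants a rectangular multiplicative depletion of
    ``depth`` within +/-``halfwidth`` of bound methylated sites in WT
    (both motifs) and the mCG-only binder (mCG only), and measures the mean
    central ln-ratio against the knockout.  The null scale comes from
    ``n_null`` independent depth-0 runs.
    """
    config = SimulationConfig(
        seed=_seed(seed, 1),
        genome_length=genome_length,
        footprint_depth=depth,
        footprint_halfwidth=halfwidth,
        library_size=library_size,
        n_replicates=n_replicates,
        bound_contexts=("CG", "CAC"),
    )
    genome = simulate.make_genome(config)
    records = simulate.simulate_wgbs(genome, config)
    cg_merged = methylation.merge_cg_strands(
        records[records["context"] == "CG"]
    )
    cat_mcg = methylation.select_sites(
        cg_merged, "CG", min_meth=1.0, min_cov=5, max_n=n_sites,
        seed=_seed(seed, 2), label="mCG",
    )
    cat_mcac = methylation.select_sites(
        records, "CAC", min_meth=0.75, min_cov=5, max_n=n_sites,
        seed=_seed(seed, 3), label="mCAC",
    )
    cat_unmeth = methylation.select_sites(
        cg_merged, "CG", exact_zero=True, min_meth=0.0, min_cov=10,
        max_n=n_sites, seed=_seed(seed, 4), label="CG_unmethylated",
    )
    catalogs = {"CG": cat_mcg, "CAC": cat_mcac}

    wt = simulate.simulate_atac(genome, catalogs, config, "WT")
    ko = simulate.simulate_atac(genome, catalogs, config, "KO")
    mm2 = simulate.simulate_atac(genome, catalogs, config, "MM2")

    def ratio_depth(num_tracks, den_tracks, catalog):
        num = _genotype_profile(num_tracks, catalog)
        den = _genotype_profile(den_tracks, catalog)
        return footprint.footprint_depth(
            footprint.footprint_ratio(num, den), core_halfwidth=halfwidth
        )

    result = {
        "n_sites": {
            "mCG": len(cat_mcg), "mCAC": len(cat_mcac),
            "unmethylated": len(cat_unmeth),
        },
        "depth_wt_ko_mcg": ratio_depth(wt, ko, cat_mcg),
        "depth_wt_ko_mcac": ratio_depth(wt, ko, cat_mcac),
        "depth_mm2_ko_mcg": ratio_depth(mm2, ko, cat_mcg),
        "depth_mm2_ko_mcac": ratio_depth(mm2, ko, cat_mcac),
        "depth_wt_ko_unmethylated": ratio_depth(wt, ko, cat_unmeth),
    }

    null_depths = []
    for i in range(n_null):
        cfg0 = config.replace(seed=_seed(seed, 10 + i), footprint_depth=0.0)
        a = simulate.simulate_atac(genome, catalogs, cfg0, "WT")
        b = simulate.simulate_atac(genome, catalogs, cfg0, "KO")
        null_depths.append(ratio_depth(a, b, cat_mcg))
    result["null_depths"] = null_depths
    result["null_sd"] = float(np.std(null_depths, ddof=1))
    return result


# ---------------------------------------------------------------------------
# deconfounding
# ---------------------------------------------------------------------------

def run_deconfound_study(
    seed: int = 0,
    n_genes: int = 15_000,
    noise_sd: float = 0.3,
    bin_size: int = 500,
) -> dict:
    """Collinearity plus planted-effect recovery at reference conditions.

    Gene methylation is sampled once (r ~ 0.9 between log10 motif counts);
    two expression contrasts are generated from it: a null-mutant-like one
    with both motif effects (beta_CG=0.2, beta_CAC=0.3) and an
    mCG-only-binder-like one with the mCG effect removed (beta_CG=0,
    beta_CAC=0.3).  Reports the confounded whole-table mCG slope on the
    latter, the binned mCG slopes that correct it, and sign recovery of
    both planted effects on the former.
    """
    config = SimulationConfig(
        seed=_seed(seed, 21),
        n_genes=n_genes,
        noise_sd=noise_sd,
        effect_sizes={"KO/WT": (0.2, 0.3), "MM2/WT": (0.0, 0.3)},
    )
    gm = simulate.simulate_gene_methylation(config)
    tables = {
        c: simulate.simulate_expression(gm, config, c)
        for c in ("KO/WT", "MM2/WT")
    }
    joined = deconfound.join_expression_methylation(tables, gm)
    r = deconfound.correlate_motifs(joined)

    confounded = deconfound.unbinned_slope(joined, "mCG", "MM2/WT")

    report = deconfound.deconfound_report(
        joined, ["KO/WT", "MM2/WT"], bin_size=bin_size
    )
    mm2_mcg = report[("MM2/WT", "mCAC")]  # mCAC bins -> mCG slopes
    slopes = mm2_mcg["slope"].to_numpy()
    mean_slope = float(slopes.mean())
    se_mean = float(slopes.std(ddof=1) / np.sqrt(len(slopes)))
    reject_frac = float((mm2_mcg["p_slope"] < 0.05).mean())

    ko_mcg = report[("KO/WT", "mCAC")]
    ko_mcac = report[("KO/WT", "mCG")]
    sign_frac_mcg = float((ko_mcg["slope"] > 0).mean())
    sign_frac_mcac = float((ko_mcac["slope"] > 0).mean())

    return {
        "n_genes": len(joined),
        "pearson_r": r,
        "confounded_mcg_slope": confounded["slope"],
        "confounded_mcg_p": confounded["p"],
        "mm2_binned_mcg_mean_slope": mean_slope,
        "mm2_binned_mcg_se": se_mean,
        "mm2_binned_mcg_reject_fraction": reject_frac,
        "mm2_n_bins": len(mm2_mcg),
        "ko_sign_recovery_mcg": sign_frac_mcg,
        "ko_sign_recovery_mcac": sign_frac_mcac,
    }


def run_calibration_study(
    seed: int = 0,
    n_seeds: int = 200,
    n_genes: int = 3_000,
    bin_size: int = 500,
    beta_cg: float = 0.2,
    noise_sd: float = 0.3,
) -> dict:
    """Type-I error and CI coverage of the within-bin slopes.

    Null pass: both motif effects zero; the fraction of interior bins
    rejecting slope=0 at alpha=0.05 estimates the size of the test.
    Coverage pass: a pure mCG effect (beta_CAC=0) makes the within-bin
    population slope exactly beta_CG, so the 95% t-interval should cover
    it 95% of the time.
    """
    rejections = []
    covered = []
    for i in range(n_seeds):
        config = SimulationConfig(
            seed=_seed(seed, 100 + i),
            n_genes=n_genes,
            noise_sd=noise_sd,
            effect_sizes={"null": (0.0, 0.0), "cg_only": (beta_cg, 0.0)},
        )
        gm = simulate.simulate_gene_methylation(config)
        tables = {
            "null": simulate.simulate_expression(gm, config, "null"),
            "cg_only": simulate.simulate_expression(gm, config, "cg_only"),
        }
        joined = deconfound.join_expression_methylation(tables, gm)
        bins = deconfound.bin_genes(joined, "mCAC", bin_size=bin_size)
        for b in bins:
            fit_null = deconfound.bin_slope(b, joined, "mCG", "null")
            rejections.append(fit_null.p_slope < 0.05)
            fit_cg = deconfound.bin_slope(b, joined, "mCG", "cg_only")
            covered.append(fit_cg.ci_low <= beta_cg <= fit_cg.ci_high)
    return {
        "n_bins": len(rejections),
        "rejection_rate": float(np.mean(rejections)),
        "ci_coverage": float(np.mean(covered)),
    }


# ---------------------------------------------------------------------------
# shared genes
# ---------------------------------------------------------------------------

def run_shared_study(seed: int = 0, n_genes: int = 15_000) -> dict:
    """Shared-dysregulation analysis on two simulated contrasts.

    Both contrasts share the mCAC effect, so genes called in both should
    change in the same direction; reports the overlap and the direction
    concordance of the shared set.
    """
    config = SimulationConfig(
        seed=_seed(seed, 51),
        n_genes=n_genes,
        effect_sizes={"KO/WT": (0.2, 0.3), "MM2/WT": (0.0, 0.3)},
    )
    gm = simulate.simulate_gene_methylation(config)
    de_ko = simulate.simulate_expression(gm, config, "KO/WT")
    de_mm2 = simulate.simulate_expression(gm, config, "MM2/WT")
    calls = [
        shared.call_significant(de_ko, contrast="KO/WT"),
        shared.call_significant(de_mm2, contrast="MM2/WT"),
    ]
    overlap = shared.overlap_analysis(calls)
    conc = shared.direction_concordance(overlap["named"]["shared"], de_ko, de_mm2)
    return {
        "n_shared": len(overlap["named"]["shared"]),
        "n_ko_only": len(overlap["named"]["KO/WT_only"]),
        "n_mm2_only": len(overlap["named"]["MM2/WT_only"]),
        "fraction_concordant": conc["fraction_concordant"],
        "slope": conc["slope"],
    }


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------

def run_frap_study(true_half_life: float = 30.0) -> dict:
    """Half-life recovery on the closed-form log-linear curve and on a
    noiseless exponential recovery, plus monotonicity over a t1/2 grid."""
    # exact log-linear series: fit must reproduce (a, b) and the closed form
    a_true, b_true = 0.2, 0.1
    dt = 1.02
    t_post = dt * np.arange(295)
    values = np.where(t_post > 0, a_true + b_true * np.log(np.maximum(t_post, dt)), 0.05)
    times = np.concatenate([-dt * np.arange(5, 0, -1), t_post])
    series = np.concatenate([np.ones(5), values])
    fit_log = frap.fit_half_life(times, series, n_prebleach=5)
    f0 = values[0]
    f_prime = float(values[-10:].mean())
    level = f0 + 0.5 * (f_prime - f0)
    closed_form = float(
        np.exp((level - a_true) / b_true) - np.exp((f0 - a_true) / b_true)
    )

    # noiseless exponential recovery at the configured true half-life
    trace = simulate.simulate_frap(true_half_life, noise_sd=0.0)
    fit_exp = frap.half_life(trace)

    grid = [10.0, 20.0, 30.0, 45.0, 60.0]
    estimates = [frap.half_life(simulate.simulate_frap(t)).half_life for t in grid]

    return {
        "log_fit_a_error": abs(fit_log.a - a_true),
        "log_fit_b_error": abs(fit_log.b - b_true),
        "log_fit_half_life": fit_log.half_life,
        "log_fit_closed_form": closed_form,
        "true_half_life": true_half_life,
        "estimated_half_life": fit_exp.half_life,
        "relative_error": abs(fit_exp.half_life - true_half_life) / true_half_life,
        "grid_true": grid,
        "grid_estimates": estimates,
        "monotone": bool(np.all(np.diff(estimates) > 0)),
    }
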
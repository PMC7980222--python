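"""Synthetic-data generators.

Every input the pipeline consumes can be fabricated here with the
statistical structure the downstream analyses assume: a random genome,
per-cytosine bisulfite calls with context-dependent beta-mixture
methylation (CG near-bimodal high, CA trinucleotides sparse/low, symmetric
CG methylation across strands), wild-type / knockout / mCG-only-binder
cut-site tracks with multiplicative depletion planted at bound methylated
sites, per-gene mCG/mCAC binding-site counts with tunable log-scale
collinearity, expression log2 fold changes generated from per-motif effect
sizes plus Gaussian noise, and photobleaching recovery traces.

All generators are pure functions of (config, seed): a fixed seed gives
byte-identical outputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import CONTEXTS, BetaMixture, SimulationConfig
from .errors import InvalidConfigurationError
from .footprint import CutSiteTrack
from .frap import FrapTrace
from .methylation import RECORD_COLUMNS, SiteCatalog, scan_contexts, with_m


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    """Independent, reproducible stream per generator."""
    # hash() is salted per process for str, so digest the stream name stably
    digest = sum(ord(c) * 31**i for i, c in enumerate(stream)) % (2**31)
    ss = np.random.SeedSequence([config.seed % (2**31), digest])
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def chromosome_lengths(config: SimulationConfig) -> dict[str, int]:
    base = config.genome_length // config.n_chromosomes
    lengths = [base] * config.n_chromosomes
    lengths[-1] += config.genome_length - base * config.n_chromosomes
    return {f"chr{i + 1}": n for i, n in enumerate(lengths)}


def make_genome(config: SimulationConfig) -> dict[str, str]:
    """I.i.d. random genome with the configured GC fraction."""
    if config.genome_length <= 0:
        raise InvalidConfigurationError("genome_length must be positive")
    rng = _rng(config, "genome")
    gc = config.gc_fraction
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = {}
    for chrom, n in chromosome_lengths(config).items():
        draws = rng.choice(alphabet, size=n, p=p)
        genome[chrom] = draws.tobytes().decode("ascii")
    return genome


# ---------------------------------------------------------------------------
# WGBS calls
# ---------------------------------------------------------------------------

def _draw_mixture(rng: np.random.Generator, mix: BetaMixture, n: int) -> np.ndarray:
    """True methylation levels from a two-component beta mixture.

    A component with mode m is Beta(1 + c*m, 1 + c*(1-m)); modes of exactly
    0 or 1 are point masses so fully (un)methylated sites are expressible.
    """
    comp_high = rng.random(n) < mix.weight
    out = np.empty(n)
    for is_high, mode in ((True, mix.high), (False, mix.low)):
        idx = np.nonzero(comp_high == is_high)[0]
        if idx.size == 0:
            continue
        if mode <= 0.0:
            out[idx] = 0.0
        elif mode >= 1.0:
            out[idx] = 1.0
        else:
            c = mix.concentration
            out[idx] = rng.beta(1 + c * mode, 1 + c * (1 - mode), size=idx.size)
    return out


def simulate_wgbs(genome: dict[str, str], config: SimulationConfig) -> pd.DataFrame:
    """Per-cytosine methylation call table (one record per cytosine per strand).

    True methylation is drawn per context from the configured beta mixture;
    symmetric CG dinucleotides share one true level across strands.
    Observed counts are meth ~ Binomial(cov, m) with cov ~ Poisson(mean).
    """
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise InvalidConfigurationError("genome is empty")
    for ctx in config.context_meth_params:
        if ctx not in CONTEXTS:
            raise InvalidConfigurationError(f"unknown context {ctx!r}")
    rng = _rng(config, "wgbs")
    sites = scan_contexts(genome)
    n = len(sites)
    true_m = np.zeros(n)
    context = sites["context"].to_numpy()
    strand = sites["strand"].to_numpy()
    pos = sites["pos"].to_numpy()
    chrom = sites["chrom"].to_numpy()

    for ctx in CONTEXTS:
        mix = config.context_meth_params.get(ctx)
        if mix is None:
            continue
        mask = context == ctx
        if ctx == "CG":
            # one draw per dinucleotide, shared across strands
            plus = mask & (strand == "+")
            minus = mask & (strand == "-")
            m_plus = _draw_mixture(rng, mix, int(plus.sum()))
            true_m[plus] = m_plus
            # minus-strand CG at reference q pairs the plus-strand C at q-1
            key_plus = pd.MultiIndex.from_arrays([chrom[plus], pos[plus]])
            lookup = pd.Series(m_plus, index=key_plus)
            key_minus = pd.MultiIndex.from_arrays([chrom[minus], pos[minus] - 1])
            paired = lookup.reindex(key_minus)
            vals = paired.to_numpy()
            missing = np.isnan(vals)
            if missing.any():  # unpaired only at chromosome edges
                vals[missing] = _draw_mixture(rng, mix, int(missing.sum()))
            true_m[minus] = vals
        else:
            true_m[mask] = _draw_mixture(rng, mix, int(mask.sum()))

    cov = rng.poisson(config.coverage_mean, size=n)
    meth = rng.binomial(cov, true_m)
    out = sites.copy()
    out["meth_count"] = meth
    out["total_count"] = cov
    return with_m(out[RECORD_COLUMNS])


# ---------------------------------------------------------------------------
# gene models and per-gene methylation
# ---------------------------------------------------------------------------

def simulate_gene_models(
    genome: dict[str, str], config: SimulationConfig
) -> pd.DataFrame:
    """Place non-overlapping genes with lognormal lengths on the genome."""
    rng = _rng(config, "genes")
    chroms = sorted(genome)
    sizes = {c: len(genome[c]) for c in chroms}
    mean_len = float(np.exp(config.gene_length_mu + config.gene_length_sigma**2 / 2))
    total = sum(sizes.values())
    spare = total - config.n_genes * mean_len
    # use half the spare for gaps so chromosome-tail waste cannot starve
    # the last placements
    mean_gap = max(20.0, 0.5 * spare / (config.n_genes + 1))
    rows = []
    ci = 0
    cursor = int(rng.exponential(mean_gap))
    while len(rows) < config.n_genes:
        if ci >= len(chroms):
            raise InvalidConfigurationError(
                f"genome too small to place {config.n_genes} genes "
                f"(placed {len(rows)})"
            )
        chrom = chroms[ci]
        length = max(50, int(rng.lognormal(config.gene_length_mu, config.gene_length_sigma)))
        if cursor + length >= sizes[chrom]:
            ci += 1
            cursor = int(rng.exponential(mean_gap))
            continue
        rows.append(
            {
                "gene_id": f"g{len(rows) + 1:05d}",
                "chrom": chrom,
                "start": cursor,
                "end": cursor + length,
                "strand": "+" if rng.random() < 0.5 else "-",
            }
        )
        cursor += length + 1 + int(rng.exponential(mean_gap))
    return pd.DataFrame(rows)


def simulate_gene_methylation(config: SimulationConfig) -> pd.DataFrame:
    """Direct per-gene sampler of mCG/mCAC binding-site counts.

    Gene lengths are lognormal; per-gene motif site counts are Poisson with
    rate (per-base density x lognormal per-gene dispersion x length).  The
    shared length factor makes log10 mCG and log10 mCAC collinear; the
    independent per-motif dispersion (density_log_sd) sets how far below 1
    the correlation sits.  The default configuration realizes Pearson
    r ~ 0.90 on the log10(count+1) scale at n = 15,000 genes.
    """
    rng = _rng(config, "gene_methylation")
    n = config.n_genes
    length = rng.lognormal(config.gene_length_mu, config.gene_length_sigma, size=n)
    disp_cg = rng.lognormal(0.0, config.density_log_sd, size=n)
    disp_cac = rng.lognormal(0.0, config.density_log_sd, size=n)
    mcg = rng.poisson(config.mcg_per_base * disp_cg * length).astype(float)
    mcac = rng.poisson(config.mcac_per_base * disp_cac * length).astype(float)
    total = mcg + mcac
    with np.errstate(invalid="ignore"):
        ratio = np.where(total > 0, mcac / total, np.nan)
    return pd.DataFrame(
        {
            "gene_id": [f"g{i + 1:05d}" for i in range(n)],
            "length": length,
            "mcg": mcg,
            "mcac": mcac,
            "total": total,
            "mcac_ratio": ratio,
        }
    )


# ---------------------------------------------------------------------------
# ATAC cut-site tracks
# ---------------------------------------------------------------------------

def _bound_contexts(config: SimulationConfig, genotype: str) -> tuple[str, ...]:
    if genotype == "KO":
        return ()
    if genotype == "WT":
        return tuple(config.bound_contexts)
    if genotype == "MM2":
        # the chimeric mCG-only binder protects mCG but not mCH sites
        return tuple(c for c in config.bound_contexts if c == "CG")
    raise InvalidConfigurationError(f"unknown genotype {genotype!r}")


def simulate_atac(
    genome: dict[str, str],
    catalog_by_context: dict[str, SiteCatalog],
    config: SimulationConfig,
    genotype: str,
) -> list[CutSiteTrack]:
    """Cut-site tracks with a rectangular multiplicative footprint.

    Background insertions are uniform over the genome; within +/-halfwidth
    of every site of every bound catalog the sampling weight is multiplied
    by (1 - depth).  Each replicate draws exactly ``library_size`` cut
    sites (multinomial over positions).
    """
    bound = _bound_contexts(config, genotype)
    for ctx in bound:
        cat = catalog_by_context.get(ctx)
        if cat is None or len(cat) == 0:
            raise InvalidConfigurationError(
                f"bound context {ctx!r} has no catalog sites"
            )
    chroms = sorted(genome)
    sizes = {c: len(genome[c]) for c in chroms}
    weights = {c: np.ones(sizes[c]) for c in chroms}
    hw = config.footprint_halfwidth
    factor = 1.0 - config.footprint_depth
    for ctx in bound:
        sites = catalog_by_context[ctx].sites
        for chrom, grp in sites.groupby("chrom", observed=True):
            w = weights.get(str(chrom))
            if w is None:
                raise InvalidConfigurationError(
                    f"catalog chromosome {chrom!r} not in genome"
                )
            for p in grp["pos"].to_numpy():
                lo = max(0, int(p) - hw)
                hi = min(sizes[str(chrom)], int(p) + hw + 1)
                w[lo:hi] *= factor

    flat = np.concatenate([weights[c] for c in chroms])
    flat = flat / flat.sum()
    offsets = np.cumsum([0] + [sizes[c] for c in chroms])
    rng = _rng(config, f"atac:{genotype}")
    tracks = []
    for rep in range(config.n_replicates):
        counts = rng.multinomial(config.library_size, flat)
        per_chrom = {
            c: counts[offsets[i] : offsets[i + 1]].astype(np.int64)
            for i, c in enumerate(chroms)
        }
        tracks.append(
            CutSiteTrack(
                counts=per_chrom,
                sample_id=f"{genotype}_rep{rep + 1}",
                genotype=genotype,
                replicate=rep + 1,
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    gene_methylation: pd.DataFrame,
    config: SimulationConfig,
    contrast: str,
) -> pd.DataFrame:
    """Differential-expression table from planted per-motif effect sizes.

    log2FC = beta_CG * log10(mcg + 1) + beta_CAC * log10(mcac + 1) + noise;
    p-values are two-sided normal tails of log2FC / noise_sd, adjusted by
    Benjamini-Hochberg.  The +1 pseudocount matches the deconfounding
    module's covariate convention.
    """
    if config.noise_sd < 0:
        raise InvalidConfigurationError("noise_sd must be >= 0")
    if contrast not in config.effect_sizes:
        raise InvalidConfigurationError(
            f"no effect sizes configured for contrast {contrast!r}"
        )
    beta_cg, beta_cac = config.effect_sizes[contrast]
    rng = _rng(config, f"expression:{contrast}")
    mcg = gene_methylation["mcg"].to_numpy(dtype=float)
    mcac = gene_methylation["mcac"].to_numpy(dtype=float)
    signal = beta_cg * np.log10(mcg + 1.0) + beta_cac * np.log10(mcac + 1.0)
    noise = rng.normal(0.0, config.noise_sd, size=len(gene_methylation))
    log2fc = signal + noise
    if config.noise_sd > 0:
        z = log2fc / config.noise_sd
        pvalue = 2.0 * stats.norm.sf(np.abs(z))
    else:
        pvalue = np.where(log2fc == 0.0, 1.0, 0.0)
    padj = multipletests(pvalue, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene_id": gene_methylation["gene_id"].to_numpy(),
            "log2fc": log2fc,
            "pvalue": pvalue,
            "padj": padj,
        }
    )


# ---------------------------------------------------------------------------
# FRAP traces
# ---------------------------------------------------------------------------

def simulate_frap(
    true_half_life: float,
    plateau: float = 0.8,
    n_points: int = 295,
    dt: float = 1.02,
    noise_sd: float = 0.0,
    seed: int = 0,
    bleach_floor: float = 0.2,
    n_prebleach: int = 5,
    background_level: float = 10.0,
    control_level: float = 110.0,
    prebleach_level: float = 210.0,
) -> FrapTrace:
    """Photobleaching recovery trace with flat control and background channels.

    Post-bleach recovery follows F(t) = F0 + (plateau - F0)(1 - 2^(-t /
    true_half_life)) on the normalized scale, so the recovery passes exactly
    halfway between floor and plateau at t = true_half_life.  The raw
    bleach-spot channel is background + (prebleach - background) * F(t)
    plus optional Gaussian noise; five prebleach frames sit at 1.0.
    """
    if true_half_life <= 0:
        raise InvalidConfigurationError("true_half_life must be positive")
    if dt <= 0:
        raise InvalidConfigurationError("dt must be positive")
    if not 0.0 <= bleach_floor < plateau <= 1.0:
        raise InvalidConfigurationError("need 0 <= bleach_floor < plateau <= 1")
    rng = np.random.default_rng(seed)
    t_pre = -dt * np.arange(n_prebleach, 0, -1)
    t_post = dt * np.arange(n_points)
    times = np.concatenate([t_pre, t_post])
    ideal = np.concatenate(
        [
            np.ones(n_prebleach),
            bleach_floor
            + (plateau - bleach_floor) * (1.0 - 2.0 ** (-t_post / true_half_life)),
        ]
    )
    if noise_sd > 0:
        ideal = ideal + rng.normal(0.0, noise_sd, size=ideal.size)
    span = prebleach_level - background_level
    frap = background_level + span * ideal
    control = np.full(times.size, control_level)
    background = np.full(times.size, background_level)
    return FrapTrace(
        times=times,
        frap=frap,
        control=control,
        background=background,
        n_prebleach=n_prebleach,
    )
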
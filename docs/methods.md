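# Methods

This note documents the models, conventions and defaults behind
`methylbind`, in the order data flows through the package.

## Coordinates and record model

All internal positions are 0-based, half-open; conversions happen only at
I/O boundaries (the methylation-call TSV is 1-based, following the
CX-report dialect; BED and gene-model TSVs are 0-based half-open).  A
methylation record is one cytosine on one strand: its context, the count
of methylated basecalls (mC) and total covering reads (C), and the derived
level mᵢ = mC/C (undefined at zero coverage; such records are carried but
rejected by every coverage threshold).

Context is read strand-forward: the base 3′ of the cytosine on its own
strand names the CN dinucleotide, and CA is refined by one more base to
CAC/CAT/CAG/CAA.  CT and CC stay dinucleotide catch-alls.  For
minus-strand cytosines "next" means reference position − 1, complemented;
this strand-forward reading is a documented convention, as is treating the
gene body as the plain interval [start, end) regardless of gene strand.

Symmetric CG dinucleotides are merged by summing mC and C across strands,
anchored at the plus-strand cytosine.  Per-gene binding-site counts,
however, sum strand-level mᵢ and halve the CG sum — one MBD-protein
molecule occupies a symmetrically methylated mCG/mCG pair — which equals
the merged-site mean when both strands are covered and stays well defined
when only one is.  This choice (strand-level, then halve) is a convention,
not something the merged/unmerged distinction in real data forces.

## Site catalogs

Default selection thresholds per catalog: mCG 100% methylation at ≥5×
(merged strands); mCAC ≥75% at ≥5×; the rarer CA/CT/CC contexts ≥50% at
≥4×; unmethylated controls exactly 0% at ≥10×.  All are overridable.  When
more sites qualify than requested, a uniform random subset is drawn from
the coordinate-sorted list with a caller-supplied seed, so catalogs are
reproducible and independent of input row order.  Genome-wide
methylation-level distributions bin covered sites into
{0%, 1–24%, 25–49%, 50–74%, 75–99%, 100%} and scale each bin count by
(total motifs in genome / covered motifs) to estimate whole-genome counts.

## Footprint profiles

Cut sites are the 5′ coordinates of reads (one per read) or both ends of a
fragment (start and end−1 under half-open coordinates).  Blacklisted
intervals and mitochondrial chromosomes are removed; when reading
alignments directly, MAPQ < 20 and secondary/duplicate records are
dropped.  No Tn5 +4/−5 offset is applied: cut sites are the raw 5′ ends.

Profiles use 601 single-base bins at offsets −300..+300 (the flanking span
plus the cytosine itself), measured in each site's orientation; sites
within 300 bp of a chromosome edge are skipped.  Flank normalization
divides every bin by the mean of the outer 100 bases of the plot, read as
50 bases per edge; `flank_width=100` gives the 100-per-edge alternative.
The processing order is: normalize each replicate, average replicates per
genotype, then take the per-bin natural log of the genotype ratio.
Division by a zero denominator bin is a hard error; a pseudocount added to
raw bins before normalization is available for sparse toy data.  The
summary statistic "footprint depth" is the mean ln-ratio over
|offset| ≤ 25 bp, matching the planted half-width of the simulator.

## Binned-slope deconfounding

Per-gene covariates are log10(count + 1); the pseudocount keeps zero-count
genes on the scale and is configurable (+1, +0.5, or drop-zeros).  The
motif–motif correlation is reported on this log scale (the scale of the
plots it mimics), with a linear-scale option.  Genes are sorted by the
binning covariate (ties broken by gene id), cut into consecutive bins of
500, a short final chunk kept, and then the first and last bins dropped as
high-variance edges — so the short chunk is always removed.  Within each
bin, ordinary least squares of log2FC on the other motif's covariate gives
the slope, a 95% interval from the t distribution with n−2 degrees of
freedom, and a two-sided p for slope = 0; homoskedastic OLS, no robust
variant.  The report adds the per-bin distribution (median, 5th/95th
percentiles) of the composition ratio mCG/total or mCAC/total
(total = mCG + mCAC).

Why binning works here: with r ≈ 0.9 collinearity, a whole-table
regression on one motif absorbs most of the other motif's effect (the
worked example shows a strongly "significant" slope for a motif whose
planted effect is exactly zero).  Within a bin the binning covariate's
variance collapses by roughly the square of the bin count, so the residual
leakage into the other motif's slope is an order of magnitude below the
slope's own standard error at bin size 500.

## Shared genes and ORA

Significance is strict padj < 0.05; genes with missing padj are never
called.  "Shared" defaults to the first call intersected with the union of
the others, with all Venn regions and pairwise intersections also
reported, because the exact set algebra between age- and symptom-matched
contrasts is a labeled option rather than a fixed rule.  Direction
concordance counts exact-zero fold changes as discordant (conservative;
zeros are measure-zero in real tables) and reports them separately.
Mann-Whitney tests use the exact null when min(n₁, n₂) ≤ 8 with no pooled
ties, otherwise the tie-corrected normal approximation with continuity
correction.  ORA intersects each gene set with the analysis universe
(by default the genes detected in all datasets), computes the upper-tail
hypergeometric P(X ≥ overlap), and applies both Bonferroni and
Benjamini-Hochberg corrections across the tested sets.

## FRAP

The double normalization divides the bleach-spot recovery (relative to its
prebleach mean) by the control cell's drift (relative to its prebleach
mean), both background-subtracted per frame; prebleach means use the five
prebleach frames.  Half-lives come from a logarithmic regression
F = a + b·ln t over post-bleach times in (0, 150] s, with t measured from
the first post-bleach frame; that frame defines the minimum F0 but is
excluded from the fit (ln 0).  The plateau F′ is the mean of the last ten
points of the whole series, not of the fit window.  The half-recovery time
is the fitted curve's crossing of (F′ − F0)/2 + F0 minus its crossing of
F0 itself (curve inversion); t(F0) = 0 is available as a flag.  Slopes
≤ 1e−12 raise a no-recovery error (a flat series regresses to a slope of
zero only up to rounding).

A known limitation, quantified by the test suite: applied to an exactly
exponential recovery sampled at 1.02 s intervals, the log-model
half-life underestimates the true value by ≈ 32% (curve-inversion mode;
≈ 19% with t(F0) = 0), invariantly to plateau, bleach depth and intensity
scale.  The estimator is exact on log-linear input and strictly monotone
in the true half-life, so it ranks conditions correctly; its absolute
values inherit the log-model's bias whenever the underlying recovery is
exponential.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analyses rely on,
at desk scale:

- **Genome**: i.i.d. bases at GC fraction 0.42 (mouse-like), default 6 Mb
  in two chromosomes — the smallest size at which every default catalog
  (mCG 100%, mCAC ≥75%, unmethylated 0%) reaches 10⁴ sites.  No repeats,
  isochores or CpG islands.
- **Methylation**: per-context two-component beta mixtures (components of
  mode m are Beta(1 + c·m, 1 + c·(1−m)), c = 30; modes 0/1 are point
  masses).  CG is near-bimodal and mostly high (high 0.95, low 0.03,
  weight 0.8); CA trinucleotides are sparse and low.  The CAC
  high-component weight (0.10) is deliberately enriched relative to real
  brain genomes so that a 6 Mb genome still yields catalog-scale sets of
  hypermethylated CAC sites.  Coverage is Poisson (mean 10), calls
  binomial, CG strands share one true level.
- **Footprint**: background insertions uniform; a rectangular
  multiplicative depletion (depth 0.5, half-width 25 bp — chosen so the
  planted recovery is analytically checkable; the kernel is pluggable) at
  every bound methylated site.  The wild type binds mCG and mCAC; the
  knockout nothing; the mCG-only binder genotype only mCG.  Replicates
  draw exactly 2×10⁶ cut sites (multinomial).  No fragment-length
  structure, nucleosome periodicity or accessibility peaks.
- **Genes**: lengths lognormal (median 20 kb, log-sd 0.5); per-gene motif
  counts Poisson with per-base densities 0.015 (mCG) and 0.005 (mCAC)
  times an independent per-gene lognormal dispersion (log-sd 0.15).  The
  shared length factor creates the log-scale collinearity; the dispersion
  sets its strength.  A delta-method calculation puts the defaults at
  r ≈ 0.90, and the realized value at n = 15,000 is 0.89–0.90; r is
  monotone in the length log-sd.
- **Expression**: log2FC = β_CG·log10(mCG+1) + β_CAC·log10(mCAC+1) +
  N(0, 0.3), with defaults β = (0.2, 0.3) for the null-mutant contrast and
  (0, 0.3) for the mCG-only-binder contrast; p-values are two-sided normal
  tails of log2FC/σ with Benjamini-Hochberg adjustment.  This fabricates
  the *semantics* of a differential-expression table without a count
  model: no mean–dispersion relationship, no independent filtering.
- **FRAP**: recovery F(t) = floor + (plateau − floor)(1 − 2^(−t/t½)) with
  five prebleach frames at 1.0 and 295 post-bleach frames 1.02 s apart;
  defaults floor 0.2, plateau 0.8 (a largely mobile nuclear protein); flat
  control and background channels.

Passing tests on these data therefore demonstrate the *procedures* —
catalog thresholds, profile arithmetic, the deconfounding logic, the
test statistics — under the stated noise and effect sizes.  They do not
demonstrate robustness to alignment artifacts, sequence composition bias,
accessibility peaks, count-model dispersion, or anomalous-diffusion
recovery shapes, none of which the generator emulates.

## Reference study sizes

The acceptance workflows use: footprint — 6 Mb genome, 10⁴-site catalogs,
three replicates of 2×10⁶ cut sites per genotype, five depth-0 runs for
the null scale; deconfounding — 15,000 genes, bins of 500 (28 interior
bins); calibration — 200 simulated datasets of 3,000 genes (800 interior
bins); FRAP — the 295-frame grid above.  Every workflow and generator is
seeded, and the whole acceptance script is a pure function of its `--seed`.
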
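# methylbind

Tools for reading methyl-CpG-binding-protein biology out of sequencing
data.  MeCP2 and related MBD proteins bind methylated cytosines not only
in the canonical CG dinucleotide but also in non-CG contexts, most notably
mCAC.  Because a neuron's per-gene counts of mCG and mCAC sites are
strongly collinear (both scale with gene length), the two motifs' effects
on transcription are easy to conflate, and the protein's occupancy at each
motif class must be read indirectly from chromatin accessibility.  This
package implements that analysis stack as a tested, reusable library:

- **Methylation catalogs** — classify each cytosine's context
  (CG / CAC / CAT / CAG / CAA / CT / CC), merge symmetric CG evidence
  across strands, build threshold-filtered site catalogs (e.g. 100%
  methylated CG at ≥5×, ≥75% methylated CAC at ≥5×, 0% controls at ≥10×),
  summarize genome-wide methylation distributions with whole-genome
  scaling, and count per-gene methylated binding sites
  (mCG = Σᵢ mᵢ / 2 over gene-body CG cytosines, mCAC = Σᵢ mᵢ over CAC,
  with mᵢ = methylated calls / total calls at site *i*).
- **ATAC-seq footprints** — infer Tn5 cut sites from the 5′ ends of reads
  or fragment ends, drop blacklist/mitochondrial signal, sum cut sites
  into 601 single-base bins spanning ±300 bp of each catalog site in its
  own orientation, normalize to the outer flanks, average replicates, and
  form the knockout-normalized profile ln(WT/KO) per bin.  A negative
  central mean ("footprint depth") is protein protection.
- **Binned-slope deconfounding** — sort genes on one motif, cut into bins
  of 500 (dropping the high-variance first and last bins), and regress
  log2 fold change on log10(count+1) of the *other* motif within each bin
  (OLS slope, 95% t-interval, two-sided p).  Holding one collinear
  covariate nearly constant isolates the other's effect, where the naive
  whole-table regression is badly confounded.
- **Shared-gene statistics** — significance calls at padj < 0.05, Venn
  region analysis, direction concordance of shared genes, Mann-Whitney
  group comparisons (exact for small tie-free samples), and hypergeometric
  over-representation analysis against GMT gene sets with Bonferroni and
  Benjamini-Hochberg corrections.
- **FRAP kinetics** — double normalization of photobleaching traces,
  N(t) = [(C̄ₚᵣₑ − bg)/(C(t) − bg)] · [(F(t) − bg)/(F̄ₚᵣₑ − bg)], and
  recovery half-lives via logarithmic regression F = a + b·ln t over
  post-bleach t ∈ (0, 150] s, with
  t½ = t((F′ − F0)·0.5 + F0) − t(F0), t(L) = exp((L − a)/b).
- **Synthetic data** — a first-class generator for every input above:
  random genomes, beta-mixture bisulfite calls with symmetric CG
  methylation, cut-site tracks with a planted multiplicative footprint at
  bound methylated sites, per-gene motif counts with tunable log-scale
  collinearity (default r ≈ 0.9), expression tables from planted motif
  effect sizes, and recovery traces.  Everything is a pure function of
  (config, seed).

## Worked example

```python
from methylbind import (SimulationConfig, make_genome, simulate_wgbs,
                        merge_cg_strands, select_sites, simulate_atac,
                        aggregate_profile, normalize_flanks, average_replicates,
                        footprint_ratio, footprint_depth,
                        simulate_gene_methylation, simulate_expression,
                        join_expression_methylation, correlate_motifs,
                        unbinned_slope, deconfound_report)

cfg = SimulationConfig(seed=7, genome_length=1_000_000, library_size=500_000)
genome = make_genome(cfg)
records = simulate_wgbs(genome, cfg)
mcg = select_sites(merge_cg_strands(records[records.context == "CG"]),
                   "CG", min_meth=1.0, min_cov=5, max_n=2000, seed=7)

catalogs = {"CG": mcg, "CAC": select_sites(records, "CAC", min_meth=0.75, min_cov=5)}
wt = simulate_atac(genome, catalogs, cfg, "WT")
ko = simulate_atac(genome, catalogs, cfg, "KO")
mean = lambda tracks: average_replicates(
    [normalize_flanks(aggregate_profile(t, mcg)) for t in tracks])
print(footprint_depth(footprint_ratio(mean(wt), mean(ko))))

gm = simulate_gene_methylation(cfg)
tables = {c: simulate_expression(gm, cfg, c) for c in ("KO/WT", "MM2/WT")}
joined = join_expression_methylation(tables, gm)
print(correlate_motifs(joined))
print(unbinned_slope(joined, "mCG", "MM2/WT"))
print(deconfound_report(joined, ["MM2/WT"])[("MM2/WT", "mCAC")]["slope"].mean())
```

prints (abridged):

```
mCG catalog: 2000 sites at 100% methylation, >=5x
WT/KO footprint depth at mCG: -0.698 (ln units; planted depletion 0.5 -> ln(0.5) = -0.693)
per-gene log10 mCG vs log10 mCAC: Pearson r = 0.891
naive mCG slope (MM2/WT, no mCG effect planted): 0.252 (p = 2.1e-117)
binned mCG slopes (mCAC bins): mean = -0.047 over 28 bins of 500 genes
```

Read: the knockout-normalized footprint recovers the planted protection
almost exactly (ln 0.5 = −0.693); the naive regression "finds" a strongly
significant mCG effect that was never planted, because mCG tracks mCAC at
r ≈ 0.89; and binning genes on mCAC before regressing on mCG correctly
returns slopes near zero.

The same pipeline is available from the shell:

```sh
methylbind simulate all --config cfg.yaml --outdir run --seed 11
methylbind catalog build --meth run/methylation.tsv --context CG \
    --min-meth 1.0 --min-cov 5 --max-n 1000 --seed 3 --out run/mcg.bed
methylbind footprint profile --cutsites run/cutsites_WT_rep1.bed \
    --catalog run/mcg.bed --chrom-sizes run/chrom_sizes.tsv --out run/wt1.tsv
methylbind footprint ratio --num run/wt.tsv --den run/ko.tsv \
    --out run/ratio.tsv --summary run/ratio.json
methylbind deconfound --de "KO/WT=run/de_KO-WT.tsv" \
    --meth run/gene_methylation.tsv --outdir run/deconf
methylbind frap fit --input run/frap_trace.csv --out run/frap.json
```

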
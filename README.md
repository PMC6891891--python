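# tilearray

Genome-wide quantification of ChIP-on-chip and BrdU-IP-on-chip tiling-array
experiments: per-probe signal statistics, enriched-cluster calling,
Monte-Carlo interval-randomization significance for feature enrichment and
region-set overlap, and average signal profiling around genomic loci (e.g.
replication origins in budding yeast).

It is written for analysts who have paired IP/SUP probe-level intensity
tables (or precomputed signal/p-value tracks in WIG/bedGraph) and want the
classic tiling-array statistics stack as a tested, scriptable library with a
synthetic-data generator for validation.

## The statistics

**Per-probe signal and p-value.** IP and SUP intensities are linearly
rescaled so each channel's genome-wide median equals a target (500 by
default). For every probe position *x*, the paired probes within a window
*x* ± *h* (*h* = 150 bp) are collected; the signal at *x* is the
Hodges–Lehmann pseudo-median of the windowed log₂(IP/SUP) ratios and the
p-value is a one-sided Wilcoxon signed-rank test of
log IP − log SUP > 0, exact for windows of ≤ 25 probes (a generating-function
convolution over midranks) and normal-approximated with continuity and tie
corrections above that.

**Cluster calling.** A probe qualifies when its signal is positive and its
p-value is below 0.2. Maximal runs of qualifying probes (merging across gaps
up to twice the median probe spacing) that span at least 600 bp become
clusters; the cluster *peak* is the position of the maximum signal within
the cluster.

**Monte-Carlo significance.** Given clusters and a feature set (e.g. the
141 active ARSs), the observed score is the number of cluster peaks falling
inside the features. The null re-places the feature intervals *N* = 1000
times under two constraints — per-chromosome interval count and length
multiset are conserved, and the re-placed intervals never overlap — using a
gap-composition construction that is exactly uniform over non-overlapping
arrangements. With null mean μ and standard deviation σ,

    z = (observed − μ) / σ,  p = 1 − Φ(z)  (enrichment direction),

together with the observed/expected ratio, an add-one empirical p-value
(1 + #{null ≥ obs})/(N + 1), and a normality diagnostic (skewness, excess
kurtosis) of the null scores. Overlap between two cluster sets uses the
total overlapping bases as the score, randomizing each set in turn against
the other and reporting both results independently.

**Average profiles.** Mean signal in 50 bp bins across loci aligned at their
interval midpoints, with 1.5–22 kb flanks; negative signal values are either
kept or set to zero before averaging.

## Worked example

The numbered scripts under `analysis/` run the whole study design on
synthetic data (a 4-chromosome 1.35 Mb genome, 40 origin-like features,
probes every 8 bp, 3-fold planted IP enrichment):

```sh
python analysis/01_simulate_experiment.py      # genome, features, probe tables
python analysis/02_probe_stats_and_clusters.py # signal/p tracks, cluster BEDs
python analysis/03_enrichment_and_overlap.py   # Monte-Carlo significance
python analysis/04_average_profiles.py         # metagene profiles
```

which prints (seed 7):

```
rep1: 44 clusters, median span 1,705 bp, max signal 1.80 -> results/clusters_rep1.bed
peaks in features: observed 40, expected 1.91 +/- 1.31, z = 29.0,
  p_normal = 1.1e-185, ratio = 20.90 (skew 0.62)
replicate overlap: 66,280 bases (Jaccard 0.86); z = 32.7 / 34.8 randomizing rep1 / rep2
negative_mode=keep: peak mean signal 1.563 at offset +350 bp over 40 loci
```

Reading: 40 of the 44 called cluster peaks land inside the 40 planted
features against an expectation of ~1.9 under random placement (a 21-fold
enrichment, z = 29); the two replicate cluster sets share 66 kb of covered
sequence, far beyond chance in both randomization directions; and the
average log₂ ratio around feature centres peaks near the centre at about
log₂ 3 ≈ 1.58, the planted effect.

The same steps are available as a console tool
(`tilearray simulate|call-clusters|enrich|overlap|profile|run`); see
`tilearray --help`.

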
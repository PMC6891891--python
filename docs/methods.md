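# Methods

This note documents the statistical model behind each stage of the
pipeline, the parameters that matter, the numerical conventions, what the
synthetic-data generator does and does not emulate, and the known
limitations.

## Coordinates and formats

All in-memory coordinates are 0-based half-open; BED is native to this
convention, while WIG and probe-table positions are converted from 1-based
on read and back on write. bedGraph intervals loaded as probe tracks are
represented by their midpoint (`start + (end - start) // 2`), a
deterministic mapping chosen because all downstream statistics are
per-position. Chromosome names are matched exactly — no `chr` aliasing —
so that naming inconsistencies surface as errors rather than silent data
loss.

## Per-probe signal and p-value estimation

The commercial software that produced the original tracks for this class of
experiment is closed; this module implements a documented estimator of the
same behaviour class (windowed rank statistics over paired intensities):

1. Each channel (IP, SUP) is linearly rescaled so its genome-wide median
   equals `target_median` (default 500 intensity units). The scaling is
   idempotent and scale-equivariant; it fixes the location of the intensity
   distribution without touching its shape.
2. For each probe position *x*, the paired probes within `bandwidth` bp
   (default 150, i.e. a ~300 bp window holding ~38 probes at 8 bp spacing)
   are collected. Positions with fewer than `min_probes` (default 4) probes
   receive signal 0 and p-value 1 rather than an unstable estimate.
3. Signal(*x*) is the Hodges–Lehmann pseudo-median — the median of all
   Walsh averages — of the windowed log₂(IP/SUP) ratios: a rank-based
   location estimate consistent with the Wilcoxon test and robust to
   outlier probes. It is antisymmetric under swapping IP and SUP.
4. p(*x*) is a Wilcoxon signed-rank test of the windowed paired differences
   log IP − log SUP, one-sided ("greater") by default because the
   experiment plants enrichment only in IP; a two-sided option exists.

### Wilcoxon implementation

Zero differences are discarded before ranking (Wilcoxon's original
treatment) and ties in |d| receive midranks. For n ≤ 25 the p-value is
exact: the null distribution of W⁺ is built by convolving the generating
function over doubled midranks (doubling makes tied midranks integral), so
ties are handled exactly rather than approximately. For n > 25 a normal
approximation with continuity correction and the standard tie-corrected
variance n(n+1)(2n+1)/24 − Σ(t³−t)/48 is used. An all-zero window is
degenerate: p = 1 with a flag. The exact branch is verified in the tests
against brute-force enumeration of all 2ⁿ sign assignments and against an
independent library implementation on tie-free data.

The windowed path is vectorized by grouping positions with equal window
size; tie-free windows share a cached exact survival table per n, and
windows containing zeros or ties fall back to the scalar routine. The
vectorized and scalar paths are cross-checked in the tests.

## Cluster calling

A position qualifies when signal > 0 and p < `max_p` (default 0.2). Maximal
runs of qualifying positions whose inter-probe gaps are at most `max_gap`
form candidate ranges `[first, last + 1)`; ranges spanning at least
`min_span` (default 600 bp) are reported. Decisions taken where the rule
admitted several readings:

- the span test applies to whole candidate ranges after gap-merging;
  sub-threshold qualifying segments are merged across gaps first, not
  discarded early;
- `max_gap` defaults to 2× the median probe spacing of the chromosome,
  adapting to array density instead of hard-coding a constant;
- the cluster end is the last qualifying probe + 1, not extended toward
  the next probe (conservative, convention-stable);
- the peak is the position of the maximum signal within the cluster,
  leftmost on ties; `min_p` is the minimum p-value inside the cluster.

Output clusters are disjoint and sorted by (chromosome order, start).

## Monte-Carlo interval randomization

The null model re-places an interval set uniformly at random per
chromosome under two constraints: the interval count and length multiset
per chromosome are conserved, and re-placed intervals never overlap each
other (they are *not* constrained against the fixed partner set). Placement
uses the gap-composition construction: the free space F = L − Σ lengths is
split into a uniformly random weak composition of k + 1 gaps (a uniform
k-subset of {0, …, F + k − 1} via stars-and-bars; rejection sampling of
distinct integers when the population is large), and the intervals are laid
down in a uniformly shuffled order. This is exactly uniform over
non-overlapping arrangements and rejection-free — verified against an
enumeration oracle for a single interval (every placement equally likely).

Scores:

- **peaks-in-ranges** — the number of cluster peaks inside the feature
  ranges (half-open; each peak counted once);
- **base overlap** — the size of the intersection of the two sets' unions,
  used for cluster-set versus cluster-set comparisons. Because mean
  cluster size inflates this score identically in the observed and
  randomized sets, the dependence cancels in the comparison.

With null draws s₁…s_N (default N = 1000): z = (obs − mean)/sd (sample sd,
ddof 1), p_normal = 1 − Φ(z) for enrichment or Φ(z) for depletion — the
direction defaults to the sign of the observed drift, and both the normal
and the add-one empirical p-value (1 + #{null at least as extreme})/(N+1)
are always reported, so no directional guess is hidden in the output. The
empirical p never underflows to zero. Normality of the null is *reported*
(skewness, excess kurtosis, a flag at |skew| > 0.5), never enforced: with
few features or few peaks the null is visibly discrete and the empirical p
is the honest summary. A degenerate null (sd = 0) sets p_normal to 1 or 0
by equality and defers to the empirical p.

For the overlap test the randomization runs twice — once per set, each
against the other set held fixed — and both results are reported
independently, to expose any bias introduced by the size and spacing
structure of either set. For `randomize="peaks"` in the enrichment test,
the peak-carrying intervals are re-placed and each peak keeps its offset
within its carrier (same-length carriers are exchangeable, so the score
distribution is well defined).

`exact_null_enumeration` provides the moments of the exact null for
instances with at most one randomized interval per chromosome by
enumerating every placement (per-chromosome scores are independent, so
moments add); it is the oracle the Monte-Carlo engine is tested against.

## Average profiles

Bins are half-open, anchored at the locus centre: bin k spans
`[c + k·res, c + (k+1)·res)` for k ∈ [−flank/res, flank/res), so the centre
bin starts exactly at the centre and the reported offset is bin start −
centre. Locus centres are interval midpoints, `floor((start+end)/2)`.
Per-locus empty bins and bins overhanging a chromosome end are excluded
(not zero-filled — zero-filling biases means on sparse arrays) and the
per-bin count of contributing loci is reported. Negative signal values are
kept by default; `negative_mode="zero"` clips them first, matching the two
conventions used for this kind of profile. Strand is ignored (replication
origins are unstranded). Loci are weighted equally regardless of probe
count.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:

| parameter | default | meaning |
|---|---|---|
| probe_spacing | 8 bp | tiling grid step |
| noise_sigma | 0.25 | sd of natural-log intensity noise |
| baseline_mu | ln 500 | mean log intensity (median ≈ normalization target) |
| effect | 3.0 | multiplicative IP enrichment inside planted regions |

SUP = exp(μ + σε), IP an independent draw times `effect` inside planted
regions: the standard lognormal (multiplicative-noise) microarray model,
which makes log-ratio statistics exact — inside a region
E[log₂(IP/SUP)] = log₂ effect with sd √2·σ/ln 2. Feature sets are placed by
the same uniform non-overlapping randomizer used for the null model; paired
interval sets with controlled overlap copy a chosen fraction of one set
and place the remainder disjointly. Every generator takes an explicit seed
and is bit-reproducible.

Two genome scales are used: 16 chromosomes / ~12 Mb (yeast-like) for
integration-scale checks, and 2 × 100 kb for unit tests. Validation runs
use feature counts of order 40–141 and 1.5 kb origin-like lengths.

What the generator does **not** emulate: probe-sequence-dependent affinity
and cross-hybridization, spatially correlated noise, replication-timing
gradients, copy-number structure, and probe dropout. Tests passing on this
model therefore demonstrate the correctness of the statistics and the
calibration of the Monte-Carlo machinery under idealized noise, not
robustness to array artefacts.

## Numerical conventions and degenerate inputs

- All randomness flows through explicitly seeded `numpy` Generators; the
  overlap test spawns two independent child streams from one seed.
  Identical seeds give bit-identical results, including JSON/BED output
  bytes (floats are written with `repr`, i.e. round-trip precision).
- Ties: cluster peak → leftmost; Wilcoxon ranks → midranks; empirical p →
  add-one rule.
- Errors are loud: empty intensity vectors, non-positive intensities,
  p-values outside [0,1], intervals off the chromosome, infeasible
  randomizations (total length > chromosome) all raise typed exceptions;
  the CLI maps them to exit codes (2 validation, 3 infeasible
  randomization, 4 I/O).

## Known limitations

- **Boundary resolution is O(bandwidth), not O(probe spacing).** A probe
  d bp outside an enriched region still has ~(bandwidth − d)/spacing
  enriched probes in its window, and under the null a fraction ≈ max_p of
  probes qualifies in bandwidth-sized correlated blocks (adjacent windows
  share almost all probes). Measured on planted 1.5 kb regions at effect 3
  with the defaults: detection is complete, and boundary errors have
  median ≈ 110 bp with a 95th percentile ≈ 270 bp. Probe-level boundary
  localisation is not achievable with a 150 bp window at p < 0.2; users
  needing sharper edges should lower the bandwidth (at the cost of
  noisier per-window tests) or post-process cluster edges.
- The normal-approximation p-value can be anti-conservative when the null
  score distribution is skewed (few features, small genomes); the reported
  skewness flag and the empirical p cover this case.
- Replicates are not modelled: tracks are analysed one experiment at a
  time and compared only through cluster-set overlap.
- The per-window test assumes exchangeable paired differences within a
  window; a real array's spatially correlated probe effects would make
  neighbouring windows even less independent than documented above.
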
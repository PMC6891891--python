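#!/usr/bin/env python
"""Monte-Carlo significance: (i) are the cluster peaks enriched within the
origin-like features (1000 interval randomizations, peaks-in-ranges score)?
(ii) do the two replicate cluster sets overlap more than chance (base-overlap
score, randomizing each set in turn)?

Writes results/enrichment.json and results/overlap.json.
"""

import argparse
import json
import os

from tilearray import McConfig, enrichment_test
from tilearray.genome_io import read_bed, read_chrom_sizes, read_clusters_bed
from tilearray.interval_mc import IntervalSet
from tilearray.pipeline import compare_conditions

HERE = os.path.dirname(os.path.abspath(__file__))
DATA = os.path.join(HERE, "..", "scratch", "analysis_data")
RESULTS = os.path.join(HERE, "..", "results")


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--n", type=int, default=1000)
    args = ap.parse_args()

    layout = read_chrom_sizes(os.path.join(DATA, "genome.chrom.sizes"))
    features = read_bed(os.path.join(DATA, "features.bed"), layout)
    clusters = read_clusters_bed(os.path.join(RESULTS, "clusters_rep1.bed"), layout)

    res = enrichment_test(clusters, features, layout,
                          McConfig(n_randomizations=args.n, seed=args.seed))
    with open(os.path.join(RESULTS, "enrichment.json"), "w") as fh:
        json.dump(res.to_dict(include_null_scores=False), fh, indent=2, sort_keys=True)
        fh.write("\n")
    print(f"peaks in features: observed {res.observed:.0f}, "
          f"expected {res.null_mean:.2f} +/- {res.null_sd:.2f}, z = {res.z:.1f}, "
          f"p_normal = {res.p_normal:.3g}, ratio = {res.ratio:.2f} "
          f"(skew {res.skewness:.2f})")

    cl_a = read_clusters_bed(os.path.join(RESULTS, "clusters_rep1.bed"), layout)
    cl_b = read_clusters_bed(os.path.join(RESULTS, "clusters_rep2.bed"), layout)
    set_a = IntervalSet([c.interval for c in cl_a], name="rep1", layout=layout)
    set_b = IntervalSet([c.interval for c in cl_b], name="rep2", layout=layout)
    rep = compare_conditions(set_a, set_b, layout,
                             McConfig(n_randomizations=args.n, seed=args.seed + 1))
    with open(os.path.join(RESULTS, "overlap.json"), "w") as fh:
        json.dump(rep, fh, indent=2, sort_keys=True)
        fh.write("\n")
    print(f"replicate overlap: {rep['observed_overlap_bases']:,} bases "
          f"(Jaccard {rep['jaccard']:.2f}); "
          f"z = {rep['randomize_a']['z']:.1f} / {rep['randomize_b']['z']:.1f} "
          f"randomizing rep1 / rep2")


if __name__ == "__main__":
    main()
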
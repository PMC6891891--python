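#!/usr/bin/env python
"""Simulate the study inputs: a multi-chromosome genome, origin-like feature
intervals, and a paired IP/SUP tiling-probe experiment with a 3-fold
enrichment planted at the features.

Writes genome.chrom.sizes, features.bed and probes.tsv (large) into
scratch/analysis_data/, plus a second probe table from an independent
replicate seed for the condition-comparison step.
"""

import argparse
import os

from tilearray import SimConfig, simulate_features, simulate_genome, simulate_probe_experiment
from tilearray.cli import _merge_ip_sup
from tilearray.genome_io import write_bed, write_chrom_sizes, write_probe_table

HERE = os.path.dirname(os.path.abspath(__file__))
DATA = os.path.join(HERE, "..", "scratch", "analysis_data")


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    args = ap.parse_args()

    os.makedirs(DATA, exist_ok=True)
    layout = simulate_genome(4, [300_000, 450_000, 250_000, 350_000])
    write_chrom_sizes(layout, os.path.join(DATA, "genome.chrom.sizes"))
    print(f"genome: {len(layout)} chromosomes, {layout.total_length:,} bp")

    features = simulate_features(layout, 40, length_mean=1500, seed=args.seed)
    write_bed(features, os.path.join(DATA, "features.bed"))
    print(f"features: {len(features)} origin-like intervals, "
          f"{features.total_bases:,} bp covered "
          f"({100 * features.total_bases / layout.total_length:.1f}% of genome)")

    for label, seed in (("probes.tsv", args.seed), ("probes_rep2.tsv", args.seed + 1)):
        ip, sup, _ = simulate_probe_experiment(
            layout, features, SimConfig(effect=3.0, seed=seed))
        merged = _merge_ip_sup(ip, sup)
        write_probe_table(merged, os.path.join(DATA, label))
        print(f"{label}: {merged.n_probes():,} probes at 8 bp spacing, "
              f"planted effect 3.0 (seed {seed})")


if __name__ == "__main__":
    main()
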
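#!/usr/bin/env python
"""Normalize the paired intensities, compute per-probe log2(IP/SUP) signal
and Wilcoxon p-values in 150 bp windows, and call enriched clusters
(signal > 0, p < 0.2, span >= 600 bp).

Reads scratch/analysis_data/, writes the signal/p-value WIG tracks there and
the cluster BED (both replicates) into results/.
"""

import argparse
import os

from tilearray import ClusterConfig, ProbeStatsConfig, call_clusters, sliding_probe_stats
from tilearray.genome_io import (
    read_chrom_sizes,
    read_probe_table,
    write_clusters_bed,
    write_wig,
)
from tilearray.pipeline import _single_value_view

HERE = os.path.dirname(os.path.abspath(__file__))
DATA = os.path.join(HERE, "..", "scratch", "analysis_data")
RESULTS = os.path.join(HERE, "..", "results")


def main():
    argparse.ArgumentParser().parse_args()
    os.makedirs(RESULTS, exist_ok=True)
    layout = read_chrom_sizes(os.path.join(DATA, "genome.chrom.sizes"))
    for rep, table in (("rep1", "probes.tsv"), ("rep2", "probes_rep2.tsv")):
        raw = read_probe_table(os.path.join(DATA, table), layout)
        stats = sliding_probe_stats(
            _single_value_view(raw, "ip"), _single_value_view(raw, "sup"),
            ProbeStatsConfig())
        write_wig(stats, "signal", os.path.join(DATA, f"signal_{rep}.wig"))
        write_wig(stats, "pvalue", os.path.join(DATA, f"pvalue_{rep}.wig"))
        clusters = call_clusters(stats, ClusterConfig())
        out = os.path.join(RESULTS, f"clusters_{rep}.bed")
        write_clusters_bed(clusters, out)
        spans = [c.interval.span for c in clusters]
        print(f"{rep}: {len(clusters)} clusters, "
              f"median span {int(sorted(spans)[len(spans) // 2]):,} bp, "
              f"max signal {max(c.max_signal for c in clusters):.2f} -> {out}")


if __name__ == "__main__":
    main()
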
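"""End-to-end orchestration: normalize -> probe stats -> clusters ->
enrichment -> average profile, with a reproducibility manifest.

The manifest is a flat key=value text file recording every config value, the
seed, SHA-256 digests of the inputs and the per-stage output paths.
Re-running with the same inputs and configs reproduces byte-identical
statistical outputs (cluster BED, enrichment JSON, profile TSV).
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass
from typing import Dict, List, Optional

from . import __version__
from .cluster_calling import ClusterConfig, call_clusters
from .genome_io import (
    GenomeLayout,
    IntervalSet,
    read_bed,
    read_chrom_sizes,
    read_probe_table,
    write_clusters_bed,
    write_wig,
)
from .interval_mc import McConfig, enrichment_test, overlap_bases, overlap_test
from .probe_stats import ProbeStatsConfig, sliding_probe_stats
from .profiling import ProfileConfig, average_profile, interval_centers, write_profile_tsv


@dataclass
class RunManifest:
    version: str
    inputs: Dict[str, str]  # path -> sha256
    config: Dict[str, object]
    outputs: Dict[str, str]  # stage -> path

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"version={self.version}\n")
            for k in sorted(self.inputs):
                fh.write(f"input.{k}={self.inputs[k]}\n")
            for k in sorted(self.config):
                fh.write(f"config.{k}={self.config[k]}\n")
            for k in sorted(self.outputs):
                fh.write(f"output.{k}={self.outputs[k]}\n")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _flat_config(prefix: str, cfg) -> Dict[str, object]:
    return {f"{prefix}.{k}": v for k, v in asdict(cfg).items()}


def run_full_pipeline(
    probe_table_path: str,
    features_bed_path: str,
    chrom_sizes_path: str,
    out_dir: str,
    probe_cfg: ProbeStatsConfig = ProbeStatsConfig(),
    cluster_cfg: ClusterConfig = ClusterConfig(),
    mc_cfg: McConfig = McConfig(),
    profile_cfg: ProfileConfig = ProfileConfig(),
) -> RunManifest:
    """Run the whole analysis on one IP/SUP probe table and one feature set.

    Writes signal/p-value WIG tracks, the cluster BED, the enrichment JSON,
    the average-profile TSV and the run manifest into ``out_dir``.
    """
    os.makedirs(out_dir, exist_ok=True)
    stage = "read inputs"
    try:
        layout = read_chrom_sizes(chrom_sizes_path)
        raw = read_probe_table(probe_table_path, layout)
        features = read_bed(features_bed_path, layout, name="features")

        stage = "probe statistics"
        ip = _single_value_view(raw, "ip")
        sup = _single_value_view(raw, "sup")
        stats = sliding_probe_stats(ip, sup, probe_cfg)
        signal_wig = os.path.join(out_dir, "signal.wig")
        pvalue_wig = os.path.join(out_dir, "pvalue.wig")
        write_wig(stats, "signal", signal_wig)
        write_wig(stats, "pvalue", pvalue_wig)

        stage = "cluster calling"
        clusters = call_clusters(stats, cluster_cfg)
        clusters_bed = os.path.join(out_dir, "clusters.bed")
        write_clusters_bed(clusters, clusters_bed)

        stage = "enrichment test"
        result = enrichment_test(clusters, features, layout, mc_cfg)
        enrichment_json = os.path.join(out_dir, "enrichment.json")
        with open(enrichment_json, "w") as fh:
            json.dump(result.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

        stage = "average profile"
        centers = interval_centers(features)
        profile = average_profile(stats, centers, profile_cfg)
        profile_tsv = os.path.join(out_dir, "profile.tsv")
        write_profile_tsv(profile, profile_tsv)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage: {stage}") from exc

    config: Dict[str, object] = {}
    for prefix, cfg in (
        ("probe_stats", probe_cfg),
        ("clusters", cluster_cfg),
        ("mc", mc_cfg),
        ("profile", profile_cfg),
    ):
        config.update(_flat_config(prefix, cfg))
    manifest = RunManifest(
        version=__version__,
        inputs={
            "probe_table": _sha256(probe_table_path),
            "features_bed": _sha256(features_bed_path),
            "chrom_sizes": _sha256(chrom_sizes_path),
        },
        config=config,
        outputs={
            "signal_wig": signal_wig,
            "pvalue_wig": pvalue_wig,
            "clusters_bed": clusters_bed,
            "enrichment_json": enrichment_json,
            "profile_tsv": profile_tsv,
        },
    )
    manifest.write(os.path.join(out_dir, "manifest.txt"))
    return manifest


def _single_value_view(track, name):
    """A ProbeTrack view exposing one value array of ``track``."""
    from .genome_io import ProbeTrack

    out = ProbeTrack(track.layout)
    for chrom in track.chroms():
        out.add_chrom(chrom, track.positions(chrom), **{name: track.values(chrom, name)})
    return out


def compare_conditions(
    a: IntervalSet,
    b: IntervalSet,
    layout: GenomeLayout,
    cfg: McConfig = McConfig(),
) -> Dict[str, object]:
    """Genome-wide overlap report between two cluster sets.

    Wraps the two-way overlap randomization test and adds descriptive
    statistics (bases covered, Jaccard index of the unions).
    """
    res_a, res_b = overlap_test(a, b, layout, cfg)
    bases_a = a.total_bases
    bases_b = b.total_bases
    inter = overlap_bases(a, b)
    union = bases_a + bases_b - inter
    return {
        "observed_overlap_bases": inter,
        "bases_a": bases_a,
        "bases_b": bases_b,
        "jaccard": inter / union if union else float("nan"),
        "randomize_a": res_a.to_dict(include_null_scores=False),
        "randomize_b": res_b.to_dict(include_null_scores=False),
    }
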
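"""Detection of enriched-signal clusters from per-position signal/p-value tracks.

A probe position qualifies when its log2(IP/SUP) signal is positive and its
p-value is below ``max_p`` (0.2 by default). Maximal runs of qualifying
positions whose inter-probe gaps do not exceed ``max_gap`` form candidate
ranges [first, last + 1); candidates at least ``min_span`` bp wide (600 by
default) are reported as clusters. The cluster peak is the position of the
highest signal inside the range, leftmost on ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .genome_io import Cluster, Interval, ProbeTrack, ValidationError


@dataclass(frozen=True)
class ClusterConfig:
    """Cluster-detection thresholds.

    min_span : minimum whole-range width in bp.
    max_p : qualifying positions need pvalue strictly below this.
    require_positive_signal : qualifying positions need signal > 0.
    max_gap : largest bp gap between successive qualifying probes merged into
        one candidate range; ``None`` means 2x the median probe spacing of the
        chromosome being processed.
    """

    min_span: int = 600
    max_p: float = 0.2
    require_positive_signal: bool = True
    max_gap: Optional[int] = None

    def __post_init__(self):
        if self.min_span <= 0:
            raise ValidationError("min_span must be > 0")
        if not (0 < self.max_p <= 1):
            raise ValidationError("max_p must be in (0, 1]")
        if self.max_gap is not None and self.max_gap < 0:
            raise ValidationError("max_gap must be >= 0")


def cluster_peak(track: ProbeTrack, interval: Interval) -> Tuple[int, float]:
    """Position and value of the maximum signal inside ``interval``.

    Ties are broken by the leftmost position. Raises if the interval contains
    no probe.
    """
    pos = track.positions(interval.chrom)
    sig = track.values(interval.chrom, "signal")
    lo = np.searchsorted(pos, interval.start, side="left")
    hi = np.searchsorted(pos, interval.end, side="left")
    if hi <= lo:
        raise ValidationError(
            f"no probe inside {interval.chrom}:{interval.start}-{interval.end}"
        )
    window = sig[lo:hi]
    k = int(np.argmax(window))  # argmax returns the first maximum: leftmost tie
    return int(pos[lo + k]), float(window[k])


def call_clusters(
    track: ProbeTrack, cfg: ClusterConfig = ClusterConfig()
) -> List[Cluster]:
    """Call enriched clusters from a track carrying signal and pvalue arrays.

    Returns clusters sorted by (chromosome order, start); output intervals are
    pairwise disjoint by construction.
    """
    clusters: List[Cluster] = []
    for chrom in track.chroms():
        pos = track.positions(chrom)
        sig = track.values(chrom, "signal")
        pval = track.values(chrom, "pvalue")
        if pos.size == 0:
            continue
        qualifies = pval < cfg.max_p
        if cfg.require_positive_signal:
            qualifies &= sig > 0
        qpos = pos[qualifies]
        if qpos.size == 0:
            continue
        if cfg.max_gap is None:
            spacing = track.median_spacing(chrom)
            max_gap = 2 * spacing if np.isfinite(spacing) else 0
        else:
            max_gap = cfg.max_gap
        # split qualifying positions where the gap exceeds max_gap
        breaks = np.flatnonzero(np.diff(qpos) > max_gap)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [qpos.size - 1]))
        for a, b in zip(starts, ends):
            first, last = int(qpos[a]), int(qpos[b])
            span = last + 1 - first
            if span < cfg.min_span:
                continue
            iv = Interval(chrom, first, last + 1)
            peak, max_sig = cluster_peak(track, iv)
            lo = np.searchsorted(pos, first, side="left")
            hi = np.searchsorted(pos, last + 1, side="left")
            min_p = float(pval[lo:hi].min())
            clusters.append(Cluster(iv, peak, max_sig, min_p))
    return clusters
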
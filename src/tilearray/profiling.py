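"""Average signal profiles around genomic loci (metagene / sitepro style).

Signals are averaged in fixed-resolution bins (50 bp by default) within a
flanking window on each side of every locus centre. Bins are half-open and
anchored at the centre: bin k spans [c + k*res, c + (k+1)*res) for
k = -flank//res .. flank//res - 1, so the reported offset of a bin is its
start minus the centre. Per-locus bins without probe data — or overhanging a
chromosome end — are excluded rather than zero-filled, and the per-bin count
of contributing loci is reported. Negative signal values can be kept or set
to zero before averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence

import numpy as np

from .genome_io import IntervalSet, ProbeTrack, ValidationError


@dataclass(frozen=True)
class ProfileConfig:
    """resolution: bp per bin; flank: bp each side of the centre;
    negative_mode: 'keep' or 'zero'."""

    resolution: int = 50
    flank: int = 6000
    negative_mode: str = "keep"

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValidationError("resolution must be > 0")
        if self.flank < self.resolution:
            raise ValidationError("flank must be >= resolution")
        if self.negative_mode not in ("keep", "zero"):
            raise ValidationError("negative_mode must be 'keep' or 'zero'")


@dataclass
class AverageProfile:
    offsets: np.ndarray  # bin start - centre, bp
    mean_signal: np.ndarray
    n_loci: int
    n_contributing: np.ndarray  # per-bin count of loci with data


def interval_centers(iset: IntervalSet) -> Dict[str, np.ndarray]:
    """Midpoint floor((start + end) / 2) of each interval, by chromosome."""
    out: Dict[str, List[int]] = {}
    for iv in iset:
        out.setdefault(iv.chrom, []).append((iv.start + iv.end) // 2)
    return {c: np.array(v, dtype=np.int64) for c, v in out.items()}


def average_profile(
    track: ProbeTrack,
    centers: Mapping[str, Sequence[int]],
    cfg: ProfileConfig = ProfileConfig(),
) -> AverageProfile:
    """Mean signal per offset bin across loci aligned at their centres."""
    n_side = cfg.flank // cfg.resolution
    n_bins = 2 * n_side
    offsets = (np.arange(n_bins) - n_side) * cfg.resolution
    sums = np.zeros(n_bins, dtype=np.float64)
    counts = np.zeros(n_bins, dtype=np.int64)

    n_loci = 0
    for chrom, cpos in centers.items():
        cpos = np.asarray(cpos, dtype=np.int64)
        n_loci += cpos.size
        if chrom not in track.chroms():
            continue
        pos = track.positions(chrom)
        sig = track.values(chrom, "signal")
        if cfg.negative_mode == "zero":
            sig = np.maximum(sig, 0.0)
        L = track.layout.length(chrom)
        csum = np.concatenate(([0.0], np.cumsum(sig)))
        for c in cpos:
            starts = c + offsets
            ends = starts + cfg.resolution
            valid = (starts >= 0) & (ends <= L)
            lo = np.searchsorted(pos, starts[valid], side="left")
            hi = np.searchsorted(pos, ends[valid], side="left")
            nprobe = hi - lo
            have = nprobe > 0
            idx = np.flatnonzero(valid)[have]
            sums[idx] += (csum[hi[have]] - csum[lo[have]]) / nprobe[have]
            counts[idx] += 1
    if n_loci == 0:
        raise ValidationError("no centres supplied")
    mean = np.full(n_bins, np.nan)
    np.divide(sums, counts, out=mean, where=counts > 0)
    return AverageProfile(offsets, mean, n_loci, counts)


def write_profile_tsv(profile: AverageProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("offset\tmean_signal\tn_contributing\n")
        for o, m, c in zip(profile.offsets, profile.mean_signal, profile.n_contributing):
            fh.write(f"{o}\t{float(m)!r}\t{c}\n")
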
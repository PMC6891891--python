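"""Synthetic tiling-array inputs: genomes, origin-like feature sets, paired
IP/SUP probe experiments with planted enrichment, and interval-set pairs with
controlled overlap.

The intensity model is lognormal — SUP = exp(mu + noise), IP an independent
draw multiplied by a constant enrichment factor inside planted regions —
which is the standard multiplicative-noise picture for microarray
intensities and makes log2-ratio statistics exact. Every generator takes an
explicit seed and uses a single local RNG stream, so outputs are
bit-reproducible.

Two genome scales are used throughout the project: a yeast-like 16-chromosome
~12 Mb layout for integration work and a tiny 2 x 100 kb layout for unit
tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .genome_io import GenomeLayout, Interval, IntervalSet, ProbeTrack, ValidationError
from .interval_mc import InfeasibleRandomizationError, randomize_intervals


@dataclass(frozen=True)
class SimConfig:
    """Probe-experiment simulation parameters.

    probe_spacing : bp between tiling probes (8 by default, the dense end of
        a yeast tiling array grid).
    noise_sigma : sd of the natural-log intensity noise.
    baseline_mu : mean natural-log intensity; exp(baseline_mu) = 500 matches
        the normalization target the pipeline scales to.
    effect : multiplicative IP enrichment inside planted regions.
    """

    probe_spacing: int = 8
    noise_sigma: float = 0.25
    baseline_mu: float = math.log(500.0)
    effect: float = 3.0
    seed: Optional[int] = None

    def __post_init__(self):
        if self.probe_spacing <= 0:
            raise ValidationError("probe_spacing must be > 0")
        if self.noise_sigma <= 0:
            raise ValidationError("noise_sigma must be > 0")
        if self.effect < 1:
            raise ValidationError("effect must be >= 1")


YEAST_LIKE_LENGTHS: Tuple[int, ...] = tuple(
    # 16 chromosomes, ~12 Mb total, spanning the size range of a small
    # fungal genome (230 kb .. 1.5 Mb)
    [
        230_000, 810_000, 320_000, 1_530_000, 580_000, 270_000, 1_090_000,
        560_000, 440_000, 750_000, 670_000, 1_080_000, 920_000, 780_000,
        1_090_000, 950_000,
    ]
)


def simulate_genome(
    n_chrom: int, chrom_lengths: Sequence[int], name_prefix: str = "chr"
) -> GenomeLayout:
    """Layout of ``n_chrom`` chromosomes with the given lengths."""
    if n_chrom <= 0:
        raise ValidationError("need at least one chromosome")
    if len(chrom_lengths) != n_chrom:
        raise ValidationError(
            f"n_chrom={n_chrom} but {len(chrom_lengths)} lengths supplied"
        )
    return GenomeLayout(
        (f"{name_prefix}{i + 1:02d}", int(l)) for i, l in enumerate(chrom_lengths)
    )


def yeast_like_genome() -> GenomeLayout:
    return simulate_genome(16, YEAST_LIKE_LENGTHS)


def simulate_features(
    layout: GenomeLayout,
    n: int,
    length_mean: int = 1500,
    seed: Optional[int] = None,
    length_sd: Optional[float] = None,
) -> IntervalSet:
    """n non-overlapping origin-like intervals with lengths around
    ``length_mean``, placed uniformly at random."""
    if n == 0:
        return IntervalSet([], name="features", layout=layout)
    rng = np.random.default_rng(seed)
    sd = length_sd if length_sd is not None else 0.1 * length_mean
    lengths = np.maximum(
        1, np.round(rng.normal(length_mean, sd, size=n)).astype(np.int64)
    )
    # allocate intervals to chromosomes proportionally to length, then place
    chrom_lengths = np.array([l for _, l in layout.chromosomes], dtype=np.float64)
    probs = chrom_lengths / chrom_lengths.sum()
    names = layout.names
    for _ in range(100):
        assignment = rng.choice(len(names), size=n, p=probs)
        ok = all(
            lengths[assignment == i].sum() <= layout.length(names[i])
            for i in range(len(names))
        )
        if ok:
            break
    else:
        raise InfeasibleRandomizationError(
            "could not pack features into the genome; reduce n or length_mean"
        )
    seeds: List[Interval] = []
    for i, name in enumerate(names):
        cur = 0
        for l in lengths[assignment == i]:
            seeds.append(Interval(name, cur, cur + int(l)))
            cur += int(l)
    placed = randomize_intervals(IntervalSet(seeds, layout=layout), layout, rng)
    return IntervalSet(list(placed), name="features", layout=layout)


def simulate_probe_experiment(
    layout: GenomeLayout,
    features: IntervalSet,
    cfg: SimConfig = SimConfig(),
) -> Tuple[ProbeTrack, ProbeTrack, IntervalSet]:
    """Paired IP/SUP probe tracks with multiplicative enrichment planted at
    the feature intervals; returns (ip, sup, truth)."""
    rng = np.random.default_rng(cfg.seed)
    by_chrom = features.by_chrom()
    ip = ProbeTrack(layout)
    sup = ProbeTrack(layout)
    for chrom, L in layout.chromosomes:
        n = L // cfg.probe_spacing
        pos = np.arange(n, dtype=np.int64) * cfg.probe_spacing
        sup_v = np.exp(cfg.baseline_mu + cfg.noise_sigma * rng.standard_normal(n))
        ip_v = np.exp(cfg.baseline_mu + cfg.noise_sigma * rng.standard_normal(n))
        arr = by_chrom.get(chrom)
        if arr is not None and arr.size:
            inside = np.zeros(n, dtype=bool)
            for s, e in arr:
                lo = np.searchsorted(pos, s, side="left")
                hi = np.searchsorted(pos, e, side="left")
                inside[lo:hi] = True
            ip_v[inside] *= cfg.effect
        ip.add_chrom(chrom, pos, ip=ip_v)
        sup.add_chrom(chrom, pos, sup=sup_v)
    truth = IntervalSet(list(features), name="truth", layout=layout)
    return ip, sup, truth


def simulate_interval_pair(
    layout: GenomeLayout,
    n_per_set: int,
    length: int,
    overlap_fraction: float,
    seed: Optional[int] = None,
) -> Tuple[IntervalSet, IntervalSet]:
    """Two interval sets with a controlled overlap: round(f * n) of b's
    intervals are exact copies of a's, the rest are placed disjointly from a."""
    if not (0.0 <= overlap_fraction <= 1.0):
        raise ValidationError("overlap_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    a = simulate_features(
        layout, n_per_set, length_mean=length, seed=int(rng.integers(2**31)),
        length_sd=0.0,
    )
    n_shared = int(round(overlap_fraction * n_per_set))
    chosen = rng.choice(n_per_set, size=n_shared, replace=False) if n_shared else []
    b_ivs: List[Interval] = [a.intervals[i] for i in chosen]
    blocked = {c: arr for c, arr in a.merged().by_chrom().items()}
    names = layout.names
    chrom_lengths = np.array([l for _, l in layout.chromosomes], dtype=np.float64)
    probs = chrom_lengths / chrom_lengths.sum()
    placed: List[Interval] = []
    attempts = 0
    while len(placed) < n_per_set - n_shared:
        attempts += 1
        if attempts > 1000 * n_per_set:
            raise InfeasibleRandomizationError(
                "could not place disjoint partner intervals; genome too crowded"
            )
        ci = int(rng.choice(len(names), p=probs))
        L = layout.length(names[ci])
        if L < length:
            continue
        s = int(rng.integers(0, L - length + 1))
        cand = Interval(names[ci], s, s + length)
        arr = blocked.get(names[ci])
        clash = False
        if arr is not None and arr.size:
            idx = np.searchsorted(arr[:, 0], cand.end, side="left")
            if idx > 0 and arr[idx - 1, 1] > cand.start:
                clash = True
        for p in placed + b_ivs:
            if p.chrom == cand.chrom and p.start < cand.end and cand.start < p.end:
                clash = True
                break
        if not clash:
            placed.append(cand)
    b = IntervalSet(b_ivs + placed, name="set_b", layout=layout)
    a = IntervalSet(list(a), name="set_a", layout=layout)
    return a, b
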
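"""Monte-Carlo significance for genomic feature enrichment and region overlap.

The null model re-places an interval set uniformly at random, chromosome by
chromosome, under two constraints: the per-chromosome interval count and
length multiset are conserved, and the re-placed intervals never overlap one
another. Placement uses the gap-composition construction — the free space is
split into a uniformly random weak composition of (count + 1) gaps and the
intervals are laid down in a uniformly shuffled order — which is exactly
uniform over non-overlapping arrangements and rejection-free.

Two scores are supported: the number of cluster peaks falling inside a
feature set ("peaks"), and the total number of overlapping bases between two
region sets ("bases"). The observed score is compared to the Monte-Carlo
null via a normal approximation (z and one-sided normal-CDF p in the drift
direction), alongside an add-one empirical p-value and the
observed/expected ratio. Normality of the null is reported as a diagnostic
(skewness, excess kurtosis), never enforced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats as sps

from .genome_io import (
    Cluster,
    GenomeLayout,
    Interval,
    IntervalSet,
    ValidationError,
    merge_intervals_arrays,
)


class InfeasibleRandomizationError(ValidationError):
    """Total interval length exceeds the chromosome; no legal placement exists."""


@dataclass(frozen=True)
class McConfig:
    """Monte-Carlo settings: number of randomizations (1000 by default),
    RNG seed, and test direction ('enrichment', 'depletion' or 'auto')."""

    n_randomizations: int = 1000
    seed: Optional[int] = None
    direction: str = "auto"
    report_empirical_p: bool = True

    def __post_init__(self):
        if self.n_randomizations < 1:
            raise ValidationError("n_randomizations must be >= 1")
        if self.direction not in ("enrichment", "depletion", "auto"):
            raise ValidationError("direction must be enrichment/depletion/auto")


@dataclass
class EnrichmentResult:
    """Observed score against its Monte-Carlo null."""

    observed: float
    null_mean: float
    null_sd: float
    z: float
    p_normal: float
    p_empirical: float
    ratio: float  # observed / null_mean; nan when null_mean == 0
    direction: str  # resolved direction actually tested
    skewness: float
    excess_kurtosis: float
    normality_suspect: bool  # |skewness| > 0.5
    degenerate: bool  # null_sd == 0
    n_randomizations: int
    null_scores: np.ndarray = field(repr=False)

    def to_dict(self, include_null_scores: bool = True) -> Dict:
        d = {
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z": self.z,
            "p_normal": self.p_normal,
            "p_empirical": self.p_empirical,
            "ratio": self.ratio,
            "direction": self.direction,
            "skewness": self.skewness,
            "excess_kurtosis": self.excess_kurtosis,
            "normality_suspect": self.normality_suspect,
            "degenerate": self.degenerate,
            "n_randomizations": self.n_randomizations,
        }
        if include_null_scores:
            d["null_scores"] = [float(x) for x in self.null_scores]
        return d


# ---------------------------------------------------------------------------
# randomization
# ---------------------------------------------------------------------------


def _random_composition(free: int, parts: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform weak composition of ``free`` into ``parts`` non-negative ints.

    Stars-and-bars: a uniform (parts-1)-subset of {0, .., free+parts-2} gives
    the bar positions. For large populations a rejection draw of distinct
    integers avoids materialising the population.
    """
    k = parts - 1
    if k == 0:
        return np.array([free], dtype=np.int64)
    pop = free + k
    if pop <= 4096 or k * k >= pop:
        bars = np.sort(rng.choice(pop, size=k, replace=False))
    else:
        while True:
            bars = rng.integers(0, pop, size=k)
            if np.unique(bars).size == k:
                bars = np.sort(bars)
                break
    gaps = np.empty(parts, dtype=np.int64)
    gaps[0] = bars[0]
    gaps[1:-1] = np.diff(bars) - 1
    gaps[-1] = pop - 1 - bars[-1]
    return gaps


def _randomize_chrom(
    lengths: np.ndarray, chrom_length: int, rng: np.random.Generator
) -> np.ndarray:
    """Random non-overlapping starts for ``lengths`` on one chromosome.

    Returns starts aligned with the (shuffled) order in which lengths are
    laid; the output is an (n, 2) array of sorted [start, end) rows.
    """
    k = lengths.size
    free = int(chrom_length - lengths.sum())
    gaps = _random_composition(free, k + 1, rng)
    order = rng.permutation(k)
    out = np.empty((k, 2), dtype=np.int64)
    cur = int(gaps[0])
    for slot, j in enumerate(order):
        l = int(lengths[j])
        out[slot, 0] = cur
        out[slot, 1] = cur + l
        cur += l + int(gaps[slot + 1])
    return out


def randomize_intervals(
    iset: IntervalSet, layout: GenomeLayout, rng: np.random.Generator
) -> IntervalSet:
    """Re-place an interval set uniformly at random, per chromosome.

    The per-chromosome interval count and length multiset are conserved; the
    output intervals are pairwise disjoint and within bounds.
    """
    new: List[Interval] = []
    for chrom, arr in iset.by_chrom().items():
        lengths = arr[:, 1] - arr[:, 0]
        L = layout.length(chrom)
        if lengths.sum() > L:
            raise InfeasibleRandomizationError(
                f"total interval length {int(lengths.sum())} exceeds chromosome "
                f"{chrom} length {L}"
            )
        placed = _randomize_chrom(lengths, L, rng)
        new.extend(Interval(chrom, int(s), int(e)) for s, e in placed)
    return IntervalSet(new, name=iset.name, layout=layout)


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------

PeaksByChrom = Mapping[str, np.ndarray]


def cluster_peaks_by_chrom(clusters: Sequence[Cluster]) -> Dict[str, np.ndarray]:
    """Peak positions of a cluster list, grouped by chromosome."""
    out: Dict[str, List[int]] = {}
    for cl in clusters:
        out.setdefault(cl.interval.chrom, []).append(cl.peak)
    return {c: np.array(sorted(v), dtype=np.int64) for c, v in out.items()}


def peaks_in_ranges(peaks: PeaksByChrom, ranges: IntervalSet) -> int:
    """Number of peak positions falling inside any range (half-open)."""
    by_chrom = merge_intervals_arrays(ranges.by_chrom())
    total = 0
    for chrom, pos in peaks.items():
        arr = by_chrom.get(chrom)
        if arr is None or arr.size == 0:
            continue
        p = np.asarray(pos, dtype=np.int64)
        idx = np.searchsorted(arr[:, 0], p, side="right") - 1
        inside = (idx >= 0) & (p < arr[np.clip(idx, 0, None), 1])
        total += int(inside.sum())
    return total


def _overlap_bases_arrays(a: np.ndarray, b: np.ndarray) -> int:
    """Intersection size of two disjoint sorted (n, 2) interval arrays."""
    if a.size == 0 or b.size == 0:
        return 0
    i = j = 0
    total = 0
    while i < len(a) and j < len(b):
        lo = max(a[i, 0], b[j, 0])
        hi = min(a[i, 1], b[j, 1])
        if hi > lo:
            total += int(hi - lo)
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return total


def overlap_bases(a: IntervalSet, b: IntervalSet) -> int:
    """Total bases in the intersection of the unions of two interval sets."""
    ma = merge_intervals_arrays(a.by_chrom())
    mb = merge_intervals_arrays(b.by_chrom())
    return sum(
        _overlap_bases_arrays(ma[c], mb[c]) for c in set(ma) & set(mb)
    )


# ---------------------------------------------------------------------------
# significance
# ---------------------------------------------------------------------------


def mc_significance(
    observed: float,
    null_scores,
    direction: str = "auto",
) -> EnrichmentResult:
    """Summarise an observed score against Monte-Carlo null draws.

    p_normal is the one-sided standard-normal tail at z in the tested
    direction; p_empirical uses the add-one rule (1 + #as-or-more-extreme) /
    (n + 1) and never underflows to zero.
    """
    null = np.asarray(null_scores, dtype=np.float64)
    n = null.size
    if n < 2:
        raise ValidationError("need at least 2 null scores")
    mean = float(null.mean())
    sd = float(null.std(ddof=1))
    if direction == "auto":
        direction = "enrichment" if observed >= mean else "depletion"
    degenerate = sd == 0.0
    if degenerate:
        z = 0.0 if observed == mean else math.copysign(math.inf, observed - mean)
        p_normal = 1.0 if observed == mean else 0.0
    else:
        z = (observed - mean) / sd
        p_normal = float(sps.norm.sf(z) if direction == "enrichment" else sps.norm.cdf(z))
    if direction == "enrichment":
        p_emp = (1.0 + float((null >= observed).sum())) / (n + 1.0)
    else:
        p_emp = (1.0 + float((null <= observed).sum())) / (n + 1.0)
    ratio = observed / mean if mean > 0 else float("nan")
    if degenerate:
        skew = kurt = 0.0
    else:
        skew = float(sps.skew(null))
        kurt = float(sps.kurtosis(null))
    return EnrichmentResult(
        observed=float(observed),
        null_mean=mean,
        null_sd=sd,
        z=float(z),
        p_normal=p_normal,
        p_empirical=p_emp,
        ratio=ratio,
        direction=direction,
        skewness=skew,
        excess_kurtosis=kurt,
        normality_suspect=abs(skew) > 0.5,
        degenerate=degenerate,
        n_randomizations=n,
        null_scores=null,
    )


PeaksSource = Union[Sequence[Cluster], PeaksByChrom]


def _as_peaks(peaks_source: PeaksSource) -> Dict[str, np.ndarray]:
    if isinstance(peaks_source, Mapping):
        return {
            c: np.asarray(v, dtype=np.int64) for c, v in peaks_source.items()
        }
    return cluster_peaks_by_chrom(list(peaks_source))


def _peak_interval_pairs(
    peaks_source: PeaksSource, layout: GenomeLayout
) -> List[Tuple[Interval, int]]:
    """(interval, peak offset) pairs: clusters keep their peak's offset inside
    the cluster; bare positions become unit intervals with offset 0."""
    if isinstance(peaks_source, Mapping):
        pairs = [
            (Interval(c, int(p), int(p) + 1).validate(layout), 0)
            for c, pos in peaks_source.items()
            for p in np.asarray(pos, dtype=np.int64)
        ]
    else:
        pairs = [
            (cl.interval.validate(layout), cl.peak - cl.interval.start)
            for cl in peaks_source
        ]
    return pairs


def enrichment_test(
    peaks_source: PeaksSource,
    features: IntervalSet,
    layout: GenomeLayout,
    cfg: McConfig = McConfig(),
    randomize: str = "features",
) -> EnrichmentResult:
    """Are the peaks enriched within the feature ranges?

    The observed score is the number of peaks inside the features. The null
    re-places the set named by ``randomize`` ('features' or 'peaks')
    ``cfg.n_randomizations`` times and rescores. Fully reproducible for a
    fixed ``cfg.seed``.
    """
    if randomize not in ("features", "peaks"):
        raise ValidationError("randomize must be 'features' or 'peaks'")
    peaks = _as_peaks(peaks_source)
    observed = peaks_in_ranges(peaks, features)
    rng = np.random.default_rng(cfg.seed)
    null = np.empty(cfg.n_randomizations, dtype=np.float64)
    if randomize == "features":
        for i in range(cfg.n_randomizations):
            null[i] = peaks_in_ranges(peaks, randomize_intervals(features, layout, rng))
    else:
        pairs = _peak_interval_pairs(peaks_source, layout)
        piv = IntervalSet([iv for iv, _ in pairs], layout=layout)
        for i in range(cfg.n_randomizations):
            placed = randomize_intervals(piv, layout, rng)
            # the length multiset is conserved per chromosome, so assigning
            # each offset to a same-length re-placed interval keeps every
            # peak inside its carrier; same-length carriers are exchangeable
            by_len: Dict[Tuple[str, int], List[int]] = {}
            for iv in placed:
                by_len.setdefault((iv.chrom, iv.span), []).append(iv.start)
            used: Dict[Tuple[str, int], int] = {}
            rpeaks: Dict[str, List[int]] = {}
            for iv, off in pairs:
                key = (iv.chrom, iv.span)
                k = used.get(key, 0)
                used[key] = k + 1
                rpeaks.setdefault(iv.chrom, []).append(by_len[key][k] + int(off))
            null[i] = peaks_in_ranges(
                {c: np.array(v, dtype=np.int64) for c, v in rpeaks.items()}, features
            )
    return mc_significance(observed, null, cfg.direction)


def overlap_test(
    a: IntervalSet,
    b: IntervalSet,
    layout: GenomeLayout,
    cfg: McConfig = McConfig(),
) -> Tuple[EnrichmentResult, EnrichmentResult]:
    """Significance of the base overlap between two region sets.

    The randomization is performed twice — once re-placing ``a`` against the
    fixed ``b``, once re-placing ``b`` against the fixed ``a`` — and the two
    results are reported independently, never combined.
    """
    observed = overlap_bases(a, b)
    ss = np.random.SeedSequence(cfg.seed)
    rng_a, rng_b = (np.random.default_rng(s) for s in ss.spawn(2))
    null_a = np.empty(cfg.n_randomizations, dtype=np.float64)
    null_b = np.empty(cfg.n_randomizations, dtype=np.float64)
    for i in range(cfg.n_randomizations):
        null_a[i] = overlap_bases(randomize_intervals(a, layout, rng_a), b)
        null_b[i] = overlap_bases(a, randomize_intervals(b, layout, rng_b))
    return (
        mc_significance(observed, null_a, cfg.direction),
        mc_significance(observed, null_b, cfg.direction),
    )


# ---------------------------------------------------------------------------
# exact small-instance oracle
# ---------------------------------------------------------------------------


def exact_null_enumeration(
    iset: IntervalSet,
    fixed,
    layout: GenomeLayout,
    score: str = "peaks",
    max_placements: int = 10_000,
) -> Tuple[float, float]:
    """Exact null mean and sd by enumerating every legal placement.

    Requires at most one randomized interval per chromosome; per-chromosome
    scores are independent, so moments add across chromosomes. ``fixed`` is a
    peaks-by-chromosome mapping for score='peaks' or an IntervalSet for
    score='bases'.
    """
    if score not in ("peaks", "bases"):
        raise ValidationError("score must be 'peaks' or 'bases'")
    by_chrom = iset.by_chrom()
    total_placements = 0
    for chrom, arr in by_chrom.items():
        if len(arr) > 1:
            raise ValidationError(
                f"exact enumeration requires <= 1 interval per chromosome "
                f"({chrom} has {len(arr)})"
            )
        total_placements += layout.length(chrom) - int(arr[0, 1] - arr[0, 0]) + 1
    if total_placements > max_placements:
        raise ValidationError(
            f"{total_placements} placements exceed the enumeration limit "
            f"{max_placements}; use the Monte-Carlo engine instead"
        )

    if score == "peaks":
        fixed_map = {c: np.asarray(v, dtype=np.int64) for c, v in fixed.items()}
    else:
        fixed_map = merge_intervals_arrays(fixed.by_chrom())

    mean = 0.0
    var = 0.0
    for chrom, arr in by_chrom.items():
        l = int(arr[0, 1] - arr[0, 0])
        L = layout.length(chrom)
        if l > L:
            raise InfeasibleRandomizationError(
                f"interval length {l} exceeds chromosome {chrom} length {L}"
            )
        coverage = np.zeros(L + 1, dtype=np.float64)
        if score == "peaks":
            pos = fixed_map.get(chrom)
            if pos is not None and pos.size:
                coverage[pos] = 1.0
        else:
            farr = fixed_map.get(chrom)
            if farr is not None:
                for s, e in farr:
                    coverage[s:e] = 1.0
        csum = np.concatenate(([0.0], np.cumsum(coverage)))
        starts = np.arange(0, L - l + 1)
        scores = csum[starts + l] - csum[starts]
        mean += float(scores.mean())
        var += float(scores.var())  # population variance: exact distribution
    return mean, math.sqrt(var)
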
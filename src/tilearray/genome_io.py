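"""Genomic data model and readers/writers for chrom.sizes, BED, WIG and probe tables.

All in-memory coordinates are 0-based half-open. BED is native to that
convention; WIG and probe-table positions are 1-based in files and converted
on read/write. Chromosome name matching is exact: no ``chr`` aliasing is ever
applied silently.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np


class ParseError(ValueError):
    """A file could not be parsed; the message carries the line number."""


class ValidationError(ValueError):
    """A coordinate or layout invariant was violated."""


# ---------------------------------------------------------------------------
# layout and intervals
# ---------------------------------------------------------------------------


class GenomeLayout:
    """Ordered chromosome names with lengths: the coordinate universe.

    Order is significant (it is preserved through every I/O round-trip and
    defines the sort order of interval sets) and names must be unique with
    strictly positive lengths.
    """

    def __init__(self, chromosomes: Iterable[Tuple[str, int]]):
        chroms = [(str(n), int(l)) for n, l in chromosomes]
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate chromosome name(s): {', '.join(dup)}")
        for n, l in chroms:
            if l <= 0:
                raise ValidationError(f"chromosome {n!r} has non-positive length {l}")
        self._chroms: Tuple[Tuple[str, int], ...] = tuple(chroms)
        self._index: Dict[str, int] = {n: i for i, (n, _) in enumerate(chroms)}
        self._length: Dict[str, int] = dict(chroms)

    @property
    def chromosomes(self) -> Tuple[Tuple[str, int], ...]:
        return self._chroms

    @property
    def names(self) -> List[str]:
        return [n for n, _ in self._chroms]

    def length(self, chrom: str) -> int:
        try:
            return self._length[chrom]
        except KeyError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    def order(self, chrom: str) -> int:
        try:
            return self._index[chrom]
        except KeyError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._index

    def __len__(self) -> int:
        return len(self._chroms)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self._chroms)

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeLayout) and self._chroms == other._chroms

    def __repr__(self) -> str:
        return f"GenomeLayout({len(self)} chromosomes, {self.total_length} bp)"


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic range, 0-based half-open [start, end)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def span(self) -> int:
        return self.end - self.start

    def validate(self, layout: GenomeLayout) -> "Interval":
        if self.chrom not in layout:
            raise ValidationError(f"interval on unknown chromosome {self.chrom!r}")
        if self.end > layout.length(self.chrom):
            raise ValidationError(
                f"interval {self.chrom}:{self.start}-{self.end} exceeds chromosome "
                f"length {layout.length(self.chrom)}"
            )
        return self


@dataclass(frozen=True)
class Cluster:
    """An enriched-signal region with its peak position and summary stats.

    ``peak`` is the genomic position of the highest estimated signal within
    the interval; ``max_signal`` is that signal (log2 IP/SUP); ``min_p`` is
    the smallest per-position p-value inside the interval.
    """

    interval: Interval
    peak: int
    max_signal: float
    min_p: float

    def __post_init__(self):
        if not (self.interval.start <= self.peak < self.interval.end):
            raise ValidationError(
                f"peak {self.peak} outside cluster "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )
        if not (0.0 <= self.min_p <= 1.0):
            raise ValidationError(f"min_p {self.min_p} outside [0, 1]")


class IntervalSet:
    """A named collection of intervals, kept sorted per chromosome by start.

    When a layout is supplied every interval is validated against it and the
    chromosome sort order follows the layout; otherwise chromosomes sort
    lexicographically.
    """

    def __init__(
        self,
        intervals: Iterable[Interval],
        name: str = "",
        layout: Optional[GenomeLayout] = None,
    ):
        ivs = list(intervals)
        if layout is not None:
            for iv in ivs:
                iv.validate(layout)
            key = lambda iv: (layout.order(iv.chrom), iv.start, iv.end)
        else:
            key = lambda iv: (iv.chrom, iv.start, iv.end)
        self.intervals: List[Interval] = sorted(ivs, key=key)
        self.name = name
        self.layout = layout

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalSet) and self.intervals == other.intervals

    def by_chrom(self) -> Dict[str, np.ndarray]:
        """Per-chromosome (n, 2) arrays of [start, end), sorted by start."""
        out: Dict[str, List[Tuple[int, int]]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append((iv.start, iv.end))
        return {c: np.array(v, dtype=np.int64).reshape(-1, 2) for c, v in out.items()}

    @property
    def total_bases(self) -> int:
        """Bases covered by the union of the intervals."""
        total = 0
        for arr in merge_intervals_arrays(self.by_chrom()).values():
            total += int((arr[:, 1] - arr[:, 0]).sum())
        return total

    def merged(self, name: Optional[str] = None) -> "IntervalSet":
        """Union of the intervals (overlapping/adjacent runs collapsed)."""
        ivs = [
            Interval(c, int(s), int(e))
            for c, arr in merge_intervals_arrays(self.by_chrom()).items()
            for s, e in arr
        ]
        return IntervalSet(ivs, name=name or self.name, layout=self.layout)


def merge_intervals_arrays(
    by_chrom: Mapping[str, np.ndarray]
) -> Dict[str, np.ndarray]:
    """Merge per-chromosome (n, 2) interval arrays into disjoint sorted unions."""
    out: Dict[str, np.ndarray] = {}
    for chrom, arr in by_chrom.items():
        if arr.size == 0:
            out[chrom] = arr.reshape(0, 2)
            continue
        order = np.lexsort((arr[:, 1], arr[:, 0]))
        arr = arr[order]
        merged: List[List[int]] = [[int(arr[0, 0]), int(arr[0, 1])]]
        for s, e in arr[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], int(e))
            else:
                merged.append([int(s), int(e)])
        out[chrom] = np.array(merged, dtype=np.int64)
    return out


# ---------------------------------------------------------------------------
# probe tracks
# ---------------------------------------------------------------------------


class ProbeTrack:
    """Per-chromosome sorted probe positions with parallel value arrays.

    Positions are 0-based, strictly increasing and within chromosome bounds.
    Typical value arrays: ``ip``/``sup`` (intensities, >= 0), ``signal``
    (log2 IP/SUP ratio) and ``pvalue`` (in [0, 1]).
    """

    def __init__(self, layout: GenomeLayout):
        self.layout = layout
        self._positions: Dict[str, np.ndarray] = {}
        self._values: Dict[str, Dict[str, np.ndarray]] = {}

    def add_chrom(self, chrom: str, positions, **values) -> None:
        if chrom not in self.layout:
            raise ValidationError(f"unknown chromosome {chrom!r}")
        pos = np.asarray(positions, dtype=np.int64)
        if pos.ndim != 1:
            raise ValidationError("positions must be a 1-D array")
        if pos.size and (np.any(np.diff(pos) <= 0)):
            raise ValidationError(f"positions on {chrom} not strictly increasing")
        if pos.size and (pos[0] < 0 or pos[-1] >= self.layout.length(chrom)):
            raise ValidationError(
                f"probe position outside chromosome {chrom} "
                f"(length {self.layout.length(chrom)})"
            )
        vals: Dict[str, np.ndarray] = {}
        for name, v in values.items():
            a = np.asarray(v, dtype=np.float64)
            if a.shape != pos.shape:
                raise ValidationError(
                    f"value array {name!r} on {chrom} has length {a.size}, "
                    f"expected {pos.size}"
                )
            if name == "pvalue" and a.size and (a.min() < 0 or a.max() > 1):
                raise ValidationError(f"pvalue outside [0, 1] on {chrom}")
            vals[name] = a
        self._positions[chrom] = pos
        self._values[chrom] = vals

    def chroms(self) -> List[str]:
        return [c for c in self.layout.names if c in self._positions]

    def positions(self, chrom: str) -> np.ndarray:
        return self._positions[chrom]

    def values(self, chrom: str, name: str) -> np.ndarray:
        try:
            return self._values[chrom][name]
        except KeyError:
            raise ValidationError(
                f"track has no value array {name!r} on chromosome {chrom}"
            ) from None

    def value_names(self) -> List[str]:
        names: List[str] = []
        for vals in self._values.values():
            for n in vals:
                if n not in names:
                    names.append(n)
        return names

    def has_values(self, name: str) -> bool:
        return all(name in self._values[c] for c in self._positions)

    def n_probes(self) -> int:
        return sum(p.size for p in self._positions.values())

    def median_spacing(self, chrom: str) -> float:
        pos = self._positions[chrom]
        if pos.size < 2:
            return float("nan")
        return float(np.median(np.diff(pos)))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_chrom_sizes(path) -> GenomeLayout:
    """Read a ``name<TAB>length`` chrom.sizes file, preserving file order."""
    chroms: List[Tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected 'name<TAB>length'")
            try:
                length = int(parts[1])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: length {parts[1]!r} is not an integer"
                ) from None
            chroms.append((parts[0], length))
    return GenomeLayout(chroms)


def write_chrom_sizes(layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for name, length in layout.chromosomes:
            fh.write(f"{name}\t{length}\n")


_BED_SKIP_PREFIXES = ("track", "browser", "#")


def read_bed(path, layout: GenomeLayout, name: str = "") -> IntervalSet:
    """Read BED3+ into a validated, per-chromosome-sorted IntervalSet.

    Columns beyond the first three are ignored; ``track``/``browser``/comment
    lines are skipped. Coordinates are 0-based half-open per the BED standard.
    """
    ivs: List[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_BED_SKIP_PREFIXES):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected at least 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            try:
                ivs.append(Interval(chrom, start, end).validate(layout))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
    return IntervalSet(ivs, name=name or str(path), layout=layout)


def write_bed(iset: IntervalSet, path) -> None:
    with open(path, "w") as fh:
        for iv in iset:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_clusters_bed(clusters: Sequence[Cluster], path) -> None:
    """Write clusters as BED6+3: name=index, score=1000*min(max_signal,1) clamped,
    then peak (single base, column 7), max_signal, min_p."""
    with open(path, "w") as fh:
        for i, cl in enumerate(clusters, start=1):
            iv = cl.interval
            score = int(round(1000 * min(max(cl.max_signal, 0.0), 1.0)))
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tcluster_{i}\t{score}\t.\t"
                f"{cl.peak}\t{cl.max_signal!r}\t{cl.min_p!r}\n"
            )


def read_clusters_bed(path, layout: GenomeLayout) -> List[Cluster]:
    """Read back a file written by :func:`write_clusters_bed`."""
    clusters: List[Cluster] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_BED_SKIP_PREFIXES):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 cluster BED columns")
            iv = Interval(parts[0], int(parts[1]), int(parts[2])).validate(layout)
            clusters.append(
                Cluster(iv, int(parts[6]), float(parts[7]), float(parts[8]))
            )
    return clusters


def read_probe_table(path, layout: GenomeLayout) -> ProbeTrack:
    """Read a TSV probe table with header columns chrom, pos, ip, sup.

    File positions are 1-based; in-memory positions are 0-based. Intensities
    must be non-negative and positions unique and sorted within chromosome.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"chrom", "pos", "ip", "sup"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(
            f"{path}: missing required column(s): {', '.join(sorted(missing))}"
        )
    if len(df) and (df["ip"].min() < 0 or df["sup"].min() < 0):
        raise ValidationError(f"{path}: negative intensities in ip/sup columns")
    track = ProbeTrack(layout)
    for chrom, grp in df.groupby("chrom", sort=False):
        pos1 = grp["pos"].to_numpy(dtype=np.int64)
        order = np.argsort(pos1, kind="stable")
        pos1 = pos1[order]
        if pos1.size and np.any(np.diff(pos1) == 0):
            raise ValidationError(f"{path}: duplicate probe positions on {chrom}")
        if pos1.size and pos1[0] < 1:
            raise ValidationError(f"{path}: probe position < 1 on {chrom}")
        track.add_chrom(
            str(chrom),
            pos1 - 1,
            ip=grp["ip"].to_numpy(dtype=np.float64)[order],
            sup=grp["sup"].to_numpy(dtype=np.float64)[order],
        )
    return track


def write_probe_table(track: ProbeTrack, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tip\tsup\n")
        for chrom in track.chroms():
            pos = track.positions(chrom)
            ip = track.values(chrom, "ip")
            sup = track.values(chrom, "sup")
            for p, a, b in zip(pos, ip, sup):
                fh.write(f"{chrom}\t{p + 1}\t{float(a)!r}\t{float(b)!r}\n")


def read_wig(path, layout: GenomeLayout, value_name: str = "signal") -> ProbeTrack:
    """Read WIG (variableStep / fixedStep) or bedGraph into a ProbeTrack.

    WIG positions are 1-based in the file and stored 0-based. bedGraph
    intervals are represented by their midpoint position
    (``start + (end - start) // 2`` in 0-based coordinates).
    """
    per_chrom: Dict[str, List[Tuple[int, float]]] = {}
    mode: Optional[str] = None
    cur_chrom: Optional[str] = None
    fixed_pos = 0
    fixed_step = 1

    def _attrs(parts: List[str]) -> Dict[str, str]:
        return dict(p.split("=", 1) for p in parts if "=" in p)

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "browser")):
                continue
            if line.startswith("track"):
                continue
            fields = line.split()
            if fields[0] == "variableStep":
                attrs = _attrs(fields[1:])
                cur_chrom = attrs.get("chrom")
                if cur_chrom is None:
                    raise ParseError(f"{path}:{lineno}: variableStep without chrom=")
                mode = "variable"
                continue
            if fields[0] == "fixedStep":
                attrs = _attrs(fields[1:])
                cur_chrom = attrs.get("chrom")
                if cur_chrom is None or "start" not in attrs:
                    raise ParseError(f"{path}:{lineno}: fixedStep needs chrom= start=")
                fixed_pos = int(attrs["start"])
                fixed_step = int(attrs.get("step", 1))
                mode = "fixed"
                continue
            if mode == "variable":
                if len(fields) < 2:
                    raise ParseError(f"{path}:{lineno}: expected 'pos value'")
                per_chrom.setdefault(cur_chrom, []).append(
                    (int(fields[0]) - 1, float(fields[1]))
                )
            elif mode == "fixed":
                per_chrom.setdefault(cur_chrom, []).append(
                    (fixed_pos - 1, float(fields[0]))
                )
                fixed_pos += fixed_step
            else:
                # bedGraph data line: chrom start end value (0-based half-open)
                if len(fields) < 4:
                    raise ParseError(
                        f"{path}:{lineno}: expected bedGraph 'chrom start end value'"
                    )
                s, e = int(fields[1]), int(fields[2])
                mid = s + (e - s) // 2
                per_chrom.setdefault(fields[0], []).append((mid, float(fields[3])))

    track = ProbeTrack(layout)
    for chrom, pairs in per_chrom.items():
        pairs.sort(key=lambda t: t[0])
        pos = np.array([p for p, _ in pairs], dtype=np.int64)
        if pos.size and np.any(np.diff(pos) == 0):
            raise ValidationError(f"{path}: duplicate positions on {chrom}")
        vals = np.array([v for _, v in pairs], dtype=np.float64)
        kwargs = {value_name: vals}
        track.add_chrom(chrom, pos, **kwargs)
    return track


def write_wig(track: ProbeTrack, value_name: str, path) -> None:
    """Write one value array as variableStep WIG with span=1 (1-based positions)."""
    with open(path, "w") as fh:
        for chrom in track.chroms():
            vals = track.values(chrom, value_name)
            fh.write(f"variableStep chrom={chrom} span=1\n")
            for p, v in zip(track.positions(chrom), vals):
                fh.write(f"{p + 1}\t{float(v)!r}\n")
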
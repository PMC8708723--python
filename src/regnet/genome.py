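"""Core coordinate system and interval algebra.

All coordinates are 0-based, half-open (BED native). One-based formats
(GTF) are converted at the reader boundary in :mod:`regnet.io`. Strand is
``+``, ``-`` or ``.`` (unstranded).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

STRANDS = ("+", "-", ".")


class ValidationError(ValueError):
    """A record violates a coordinate or model invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chromosome name must be non-empty")
        if self.start < 0:
            raise ValidationError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end must be > start, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Midpoint: start + floor(length / 2)."""
        return self.start + self.length // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class Peak:
    """A ChIP-seq peak call: an interval plus score, optional summit, rank.

    ``score`` is whatever the caller treats as peak strength (signal value
    or -log10 q); ``rank`` is 1 for the strongest peak of its replicate.
    The peak *center* is the summit when present, else the midpoint —
    the summit is preferred because asymmetric peaks have off-center
    binding modes.
    """

    interval: GenomicInterval
    name: str = ""
    score: float = 0.0
    summit_offset: int | None = None
    rank: int | None = None

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValidationError(f"peak score must be nonnegative, got {self.score}")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.interval.length
        ):
            raise ValidationError(
                f"summit offset {self.summit_offset} outside peak of length "
                f"{self.interval.length}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def center(self) -> int:
        if self.summit_offset is not None:
            return self.interval.start + self.summit_offset
        return self.interval.center


@dataclass(frozen=True)
class TssRecord:
    """A transcription start site of a gene."""

    gene_id: str
    chrom: str
    position: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")
        if self.position < 0:
            raise ValidationError(f"TSS position must be >= 0, got {self.position}")
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}")


class Genome:
    """Chromosome names/lengths plus an optional sequence accessor."""

    def __init__(self, chrom_sizes: Mapping[str, int], sequences=None) -> None:
        for name, length in chrom_sizes.items():
            if length <= 0:
                raise ValidationError(f"chromosome {name} has non-positive length {length}")
        self.chrom_sizes = dict(chrom_sizes)
        self._sequences = sequences  # mapping chrom -> str, or pyfaidx.Fasta

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_sizes

    def __iter__(self):
        return iter(self.chrom_sizes)

    def length_of(self, chrom: str) -> int:
        try:
            return self.chrom_sizes[chrom]
        except KeyError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    def contains_interval(self, iv: GenomicInterval) -> bool:
        return iv.chrom in self.chrom_sizes and iv.end <= self.chrom_sizes[iv.chrom]

    def validate_interval(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self.chrom_sizes:
            raise ValidationError(f"interval on unknown chromosome {iv.chrom!r}")
        if iv.end > self.chrom_sizes[iv.chrom]:
            raise ValidationError(
                f"interval {iv} exceeds chromosome length {self.chrom_sizes[iv.chrom]}"
            )

    @property
    def has_sequence(self) -> bool:
        return self._sequences is not None

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Fetch sequence for [start, end), uppercased."""
        if self._sequences is None:
            raise ValidationError("genome has no sequence accessor")
        seq = self._sequences[chrom]
        if not isinstance(seq, str):  # pyfaidx.FastaRecord supports slicing
            return str(seq[start:end]).upper()
        return seq[start:end].upper()


class SignalTrack:
    """Piecewise-constant coverage: sorted non-overlapping scored intervals.

    Bases not covered by any interval are treated as signal 0 by the
    aggregation methods (bedGraph convention).
    """

    def __init__(self, data: Mapping[str, tuple] | None = None) -> None:
        # chrom -> (starts, ends, values) as numpy arrays
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if data:
            for chrom, (starts, ends, values) in data.items():
                self.set_chrom(chrom, starts, ends, values)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, int, float]]
    ) -> "SignalTrack":
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            per_chrom.setdefault(chrom, []).append((start, end, value))
        track = cls()
        for chrom, rows in per_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            values = np.array([r[2] for r in rows], dtype=float)
            track.set_chrom(chrom, starts, ends, values)
        return track

    def set_chrom(self, chrom: str, starts, ends, values) -> None:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        values = np.asarray(values, dtype=float)
        if not (len(starts) == len(ends) == len(values)):
            raise ValidationError("starts/ends/values length mismatch")
        if np.any(ends <= starts):
            raise ValidationError(f"empty or inverted interval in track on {chrom}")
        if np.any(starts[1:] < ends[:-1]):
            raise ValidationError(f"track intervals overlap or are unsorted on {chrom}")
        if not np.all(np.isfinite(values)):
            raise ValidationError(f"non-finite track value on {chrom}")
        self._data[chrom] = (starts, ends, values)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._data)

    def records(self) -> Iterable[tuple[str, int, int, float]]:
        for chrom in self.chroms:
            starts, ends, values = self._data[chrom]
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)

    def _segments(self, chrom: str, start: int, end: int):
        """Covered (sub)segments of [start, end) with their values."""
        if chrom not in self._data:
            return np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0)
        starts, ends, values = self._data[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0)
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        return s, e, values[lo:hi]

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean over [start, end); uncovered bases count as 0."""
        if end <= start:
            raise ValidationError("empty query window")
        s, e, v = self._segments(chrom, start, end)
        if len(v) == 0:
            return 0.0
        return float(np.sum((e - s) * v) / (end - start))

    def max_over(self, chrom: str, start: int, end: int) -> float:
        """Max value over [start, end); uncovered bases count as 0."""
        s, e, v = self._segments(chrom, start, end)
        covered = int(np.sum(e - s))
        m = float(np.max(v)) if len(v) else 0.0
        if covered < end - start:
            m = max(m, 0.0)
        return m


def merge_intervals(
    intervals: Iterable[GenomicInterval], genome: Genome | None = None
) -> list[GenomicInterval]:
    """Merge into a disjoint sorted set; touching intervals (end == start) merge.

    Union base coverage is preserved exactly. Strand is dropped (merged
    intervals are unstranded).
    """
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    if genome is not None:
        for iv in ivs:
            genome.validate_interval(iv)
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


class IntervalIndex:
    """Sorted per-chromosome index for half-open overlap queries."""

    def __init__(self, subjects: Sequence) -> None:
        # subjects may be GenomicInterval or objects with .interval
        self.subjects = list(subjects)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        per_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for idx, s in enumerate(self.subjects):
            iv = s.interval if hasattr(s, "interval") else s
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, idx))
        for chrom, rows in per_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            idxs = np.array([r[2] for r in rows], dtype=np.int64)
            # running max of ends enables an early-exit left bound
            self._by_chrom[chrom] = (starts, ends, idxs)

    def query(self, query: GenomicInterval) -> list[tuple[object, int]]:
        """All subjects sharing >= 1 bp with ``query`` plus the overlap size."""
        if query.chrom not in self._by_chrom:
            return []
        starts, ends, idxs = self._by_chrom[query.chrom]
        hi = int(np.searchsorted(starts, query.end, side="left"))
        if hi == 0:
            return []
        mask = ends[:hi] > query.start
        out = []
        for start, end, idx in zip(starts[:hi][mask], ends[:hi][mask], idxs[:hi][mask]):
            ov = min(int(end), query.end) - max(int(start), query.start)
            out.append((self.subjects[idx], ov))
        return out


def overlap_query(query: GenomicInterval, subjects: Sequence) -> list[tuple[object, int]]:
    """One-shot overlap query; build an :class:`IntervalIndex` for repeated use."""
    return IntervalIndex(subjects).query(query)


def distance_to_nearest_tss(
    peak: Peak | GenomicInterval, tss_set: Sequence[TssRecord]
) -> tuple[str, int]:
    """Nearest TSS by center-to-center distance.

    Returns ``(gene_id, signed_distance)`` where the magnitude is the
    minimal |peak center - TSS position| and the sign is relative to the
    gene: negative = peak upstream of the TSS, positive = downstream
    (strand-aware; unstranded TSS treated as '+'). Ties break to the
    lexicographically smaller gene_id.
    """
    if not tss_set:
        raise ValidationError("TSS set is empty")
    chrom = peak.chrom if isinstance(peak, Peak) else peak.chrom
    center = peak.center
    candidates = [t for t in tss_set if t.chrom == chrom]
    if not candidates:
        raise ValidationError(f"no TSS on chromosome {chrom!r}")
    best = min(candidates, key=lambda t: (abs(center - t.position), t.gene_id))
    raw = center - best.position
    signed = -raw if best.strand == "-" else raw
    return best.gene_id, signed


def nearest_tss_distance(center: int, chrom: str, tss_set: Sequence[TssRecord]) -> float:
    """Unsigned distance from a point to the nearest TSS; inf when none on chrom."""
    positions = [t.position for t in tss_set if t.chrom == chrom]
    if not positions:
        return float("inf")
    positions.sort()
    i = bisect.bisect_left(positions, center)
    best = float("inf")
    if i < len(positions):
        best = min(best, abs(positions[i] - center))
    if i > 0:
        best = min(best, abs(positions[i - 1] - center))
    return float(best)


def assign_ranks(peaks: Sequence[Peak]) -> list[Peak]:
    """Assign 1-based ranks by descending score (ties by genomic order)."""
    order = sorted(
        range(len(peaks)),
        key=lambda i: (-peaks[i].score, peaks[i].interval, peaks[i].name),
    )
    for rank, i in enumerate(order, start=1):
        peaks[i].rank = rank
    return list(peaks)


def sort_peaks(peaks: Iterable[Peak]) -> list[Peak]:
    return sorted(peaks, key=lambda p: (p.chrom, p.start, p.end, p.name))
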
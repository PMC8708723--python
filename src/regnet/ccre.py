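"""Candidate cis-regulatory element (cCRE) classification and peak annotation.

Elements are classified into the mutually exclusive SCREEN-style classes
from their DNase / H3K4me3 / H3K27ac max-z scores and their center-to-TSS
distance, applied with precedence PLS > pELS > dELS > DNase-H3K4me3 >
DNase-only > unclassified:

* PLS  — center within 200 bp of a TSS, DNase high, H3K4me3 high;
* ELS  — DNase high and H3K27ac high (not PLS); proximal (pELS) when the
  center is within 2 kb of a TSS, else distal (dELS);
* DNase-H3K4me3 — DNase high, H3K4me3 high, H3K27ac low, > 200 bp from a TSS;
* DNase-only — DNase high, both histone marks low.

A peak set is annotated either against a pre-classified catalog
(largest-overlap assignment, the default path) or directly by the rule
above using per-peak signals (the distance-rule path).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .genome import (
    GenomicInterval,
    IntervalIndex,
    Peak,
    SignalTrack,
    TssRecord,
    ValidationError,
    nearest_tss_distance,
)

ASSAYS = ("DNase", "H3K4me3", "H3K27ac")


class CcreClass(str, Enum):
    PLS = "PLS"
    PELS = "pELS"
    DELS = "dELS"
    DNASE_H3K4ME3 = "DNase-H3K4me3"
    DNASE_ONLY = "DNase-only"
    UNCLASSIFIED = "unclassified"

    def __str__(self) -> str:
        return self.value


#: classes that count as promoter- or enhancer-like signatures
REGULATORY_CLASSES = frozenset({CcreClass.PLS, CcreClass.PELS, CcreClass.DELS})


@dataclass(frozen=True)
class AssaySignals:
    """Per-element max-z scores for the three classifying assays."""

    dnase: float
    h3k4me3: float
    h3k27ac: float

    def __post_init__(self) -> None:
        for assay, v in zip(ASSAYS, (self.dnase, self.h3k4me3, self.h3k27ac)):
            if v is None or not np.isfinite(v):
                raise ValidationError(f"missing or non-finite signal for assay {assay}")


@dataclass
class CcreParams:
    """Distance and z-score thresholds of the classifier.

    ``high_z`` / ``low_z`` form a single cut by default (1.64, the normal
    95th percentile); a z-score is "high" when >= high_z and "low" when
    < low_z, so low_z < high_z opens an ambiguity band in which neither
    holds.
    """

    tss_proximal_bp: int = 200
    els_proximal_bp: int = 2000
    high_z: float = 1.64
    low_z: float = 1.64

    def __post_init__(self) -> None:
        if self.tss_proximal_bp <= 0 or self.els_proximal_bp <= 0:
            raise ValidationError("distance thresholds must be positive")
        if self.low_z > self.high_z:
            raise ValidationError("low_z must be <= high_z")


@dataclass
class CcreRecord:
    """A catalog element: interval, signals, and its resolved class."""

    interval: GenomicInterval
    signals: AssaySignals | None = None
    ccre_class: CcreClass = CcreClass.UNCLASSIFIED


def compute_max_z(
    elements: Sequence[GenomicInterval], track: SignalTrack
) -> np.ndarray:
    """Standardized per-element max signal (the SCREEN "max-z" statistic).

    The max of the track over each element is standardized across the
    element universe (population sd), so the result has mean 0 and sd 1.
    """
    if len(elements) < 2:
        raise ValidationError("need >= 2 elements to standardize max signals")
    maxima = np.array(
        [track.max_over(iv.chrom, iv.start, iv.end) for iv in elements], dtype=float
    )
    sd = float(np.std(maxima))
    if sd == 0:
        raise ValidationError(
            "zero variance of element max signals; check that the track varies "
            "across the element universe"
        )
    return (maxima - maxima.mean()) / sd


def classify_element(
    element: GenomicInterval | Peak,
    signals: AssaySignals,
    tss_set: Sequence[TssRecord],
    params: CcreParams | None = None,
) -> CcreClass:
    """Classify one element; total function, precedence-resolved."""
    params = params or CcreParams()
    center = element.center
    d = nearest_tss_distance(center, element.chrom, tss_set)

    def high(z: float) -> bool:
        return z >= params.high_z

    def low(z: float) -> bool:
        return z < params.low_z

    s = signals
    if d <= params.tss_proximal_bp and high(s.dnase) and high(s.h3k4me3):
        return CcreClass.PLS
    if high(s.dnase) and high(s.h3k27ac):
        return CcreClass.PELS if d <= params.els_proximal_bp else CcreClass.DELS
    if high(s.dnase) and high(s.h3k4me3) and low(s.h3k27ac) and d > params.tss_proximal_bp:
        return CcreClass.DNASE_H3K4ME3
    if high(s.dnase) and low(s.h3k4me3) and low(s.h3k27ac):
        return CcreClass.DNASE_ONLY
    return CcreClass.UNCLASSIFIED


def classify_catalog(
    records: Sequence[CcreRecord],
    tss_set: Sequence[TssRecord],
    params: CcreParams | None = None,
) -> list[CcreRecord]:
    """Resolve the class of every catalog element in place (and return it)."""
    for rec in records:
        if rec.signals is None:
            raise ValidationError(
                f"element {rec.interval} has no assay signals to classify from"
            )
        rec.ccre_class = classify_element(rec.interval, rec.signals, tss_set, params)
    return list(records)


def assign_peak_classes(
    peaks: Sequence[Peak], catalog: Sequence[CcreRecord]
) -> dict[str, CcreClass]:
    """Assign each peak the class of its largest-overlap catalog element.

    Ties break by genomic order of the element; a peak overlapping no
    element is unclassified. Keys are peak names (must be unique).
    """
    names = [p.name for p in peaks]
    if len(set(names)) != len(names):
        raise ValidationError("peak names must be unique for class assignment")
    index = IntervalIndex([r.interval for r in catalog])
    by_iv = {r.interval: r for r in catalog}
    out: dict[str, CcreClass] = {}
    for p in peaks:
        hits = index.query(p.interval)
        if not hits:
            out[p.name] = CcreClass.UNCLASSIFIED
            continue
        best_iv, _ = max(hits, key=lambda h: (h[1], (-h[0].start, -h[0].end)))
        # max with reversed coordinate key == largest overlap, ties to
        # genomically first element
        out[p.name] = by_iv[best_iv].ccre_class
    return out


def classify_peaks_by_rule(
    peaks: Sequence[Peak],
    signals: Mapping[str, AssaySignals],
    tss_set: Sequence[TssRecord],
    params: CcreParams | None = None,
) -> dict[str, CcreClass]:
    """Distance-rule path: classify peaks directly from per-peak signals."""
    out = {}
    for p in peaks:
        if p.name not in signals:
            raise ValidationError(f"no assay signals for peak {p.name!r}")
        out[p.name] = classify_element(p, signals[p.name], tss_set, params)
    return out


def class_distribution(classes: Mapping[str, CcreClass]) -> dict[CcreClass, float]:
    """Fraction of peaks per class over all six classes (sums to 1)."""
    n = len(classes)
    if n == 0:
        return {c: 0.0 for c in CcreClass}
    counts = {c: 0 for c in CcreClass}
    for c in classes.values():
        counts[c] += 1
    return {c: counts[c] / n for c in CcreClass}


def peakset_class_distribution(
    peaks: Sequence[Peak], catalog: Sequence[CcreRecord]
) -> tuple[dict[str, CcreClass], dict[CcreClass, float]]:
    """Per-peak classes (catalog-overlap path) plus the class fractions."""
    classes = assign_peak_classes(peaks, catalog)
    return classes, class_distribution(classes)


def signal_matrix(
    peaks: Sequence[Peak],
    track: SignalTrack,
    flank_bp: int = 2500,
    bin_bp: int = 50,
    genome=None,
) -> tuple[np.ndarray, list[int]]:
    """Peaks x bins matrix of mean signal around peak centers.

    Bin j of row i is the mean track value in the j-th ``bin_bp`` window
    of [center - flank, center + flank) for peak i. Rows are sorted by
    descending row mean (deepTools-style heatmap order); the returned
    index list maps rows back to the input peak order. Bins falling
    outside the chromosome are NaN ("absent"), not zero.
    """
    if flank_bp % bin_bp != 0:
        raise ValidationError("flank_bp must be divisible by bin_bp")
    ncols = 2 * flank_bp // bin_bp
    mat = np.full((len(peaks), ncols), np.nan)
    for i, p in enumerate(peaks):
        left = p.center - flank_bp
        chrom_len = genome.length_of(p.chrom) if genome is not None else None
        for j in range(ncols):
            s = left + j * bin_bp
            e = s + bin_bp
            if e <= 0 or (chrom_len is not None and s >= chrom_len):
                continue
            cs = max(s, 0)
            ce = min(e, chrom_len) if chrom_len is not None else e
            if ce - cs < bin_bp:
                continue  # partially clipped bin counts as absent
            mat[i, j] = track.mean_over(p.chrom, cs, ce)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        row_means = np.nanmean(mat, axis=1)
    row_means = np.where(np.isnan(row_means), -np.inf, row_means)
    order = list(np.argsort(-row_means, kind="stable"))
    return mat[order], order
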
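"""High-confidence consensus peaks from two biological replicates.

A simplified, fully documented reproducibility rule standing in the role
of the IDR "conservative set": peaks from the two replicates are matched
one-to-one by reciprocal overlap, matched pairs are optionally restricted
to the top-ranked fraction of each replicate, and the Spearman correlation
of ranks across matched pairs is reported as a replicate-concordance
diagnostic (a warning is raised when it falls below a threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genome import GenomicInterval, IntervalIndex, Peak, ValidationError, sort_peaks


class ConcordanceWarning(UserWarning):
    """Replicate rank concordance below the configured threshold."""


@dataclass
class ConsensusParams:
    """Thresholds of the simplified reproducibility rule.

    min_reciprocal_overlap
        Fraction of *each* member's length that the pair overlap must
        reach (reciprocal-overlap matching).
    rank_correlation_min
        Spearman rank correlation across matched pairs below which the
        replicate pair is flagged discordant.
    max_rank_fraction
        Only pairs whose both members sit in this top fraction of their
        replicate's score ranking are retained.
    """

    min_reciprocal_overlap: float = 0.5
    rank_correlation_min: float = 0.5
    max_rank_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.min_reciprocal_overlap <= 1):
            raise ValidationError("min_reciprocal_overlap must be in (0, 1]")
        if not (-1 <= self.rank_correlation_min <= 1):
            raise ValidationError("rank_correlation_min must be in [-1, 1]")
        if not (0 < self.max_rank_fraction <= 1):
            raise ValidationError("max_rank_fraction must be in (0, 1]")


@dataclass
class ConsensusPeak:
    """A reproducible peak: the span of one member from each replicate."""

    interval: GenomicInterval
    member_a: Peak
    member_b: Peak
    combined_score: float
    reproducibility: float  # min over members of (1 - rank/set size)

    @property
    def name(self) -> str:
        return f"{self.member_a.name}|{self.member_b.name}"


@dataclass
class ConsensusResult:
    peaks: list[ConsensusPeak] = field(default_factory=list)
    rank_correlation: float = float("nan")
    concordant: bool = True
    n_matched: int = 0


def pair_replicates(
    rep_a: list[Peak], rep_b: list[Peak], params: ConsensusParams | None = None
) -> list[tuple[Peak, Peak]]:
    """One-to-one matching of replicate peaks by reciprocal overlap.

    Candidate pairs must overlap by at least ``min_reciprocal_overlap`` of
    each member's length; pairs are accepted greedily by descending mean
    score (ties broken by genomic order), each peak used at most once.
    """
    params = params or ConsensusParams()
    if not rep_a or not rep_b:
        return []
    index_b = IntervalIndex(rep_b)
    candidates = []
    for a in rep_a:
        for b, ov in index_b.query(a.interval):
            if (
                ov / a.interval.length >= params.min_reciprocal_overlap
                and ov / b.interval.length >= params.min_reciprocal_overlap
            ):
                candidates.append((a, b))
    candidates.sort(
        key=lambda ab: (
            -(ab[0].score + ab[1].score) / 2.0,
            ab[0].interval,
            ab[1].interval,
            ab[0].name,
            ab[1].name,
        )
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    matching = []
    for a, b in candidates:
        if id(a) in used_a or id(b) in used_b:
            continue
        used_a.add(id(a))
        used_b.add(id(b))
        matching.append((a, b))
    matching.sort(key=lambda ab: (ab[0].chrom, ab[0].start, ab[0].end, ab[0].name))
    return matching


def consensus_set(
    matching: list[tuple[Peak, Peak]],
    size_a: int,
    size_b: int,
    params: ConsensusParams | None = None,
) -> ConsensusResult:
    """Retain top-ranked matched pairs and report replicate concordance."""
    params = params or ConsensusParams()
    result = ConsensusResult(n_matched=len(matching))
    if not matching:
        return result
    ranks_a = np.array([a.rank for a, _ in matching], dtype=float)
    ranks_b = np.array([b.rank for _, b in matching], dtype=float)
    if np.any(np.isnan(ranks_a)) or np.any(np.isnan(ranks_b)):
        raise ValidationError("all matched peaks must carry ranks")
    if len(matching) >= 2 and np.std(ranks_a) > 0 and np.std(ranks_b) > 0:
        rho = float(stats.spearmanr(ranks_a, ranks_b).statistic)
    else:
        rho = 1.0
    result.rank_correlation = rho
    if rho < params.rank_correlation_min:
        result.concordant = False
        warnings.warn(
            f"replicate rank correlation {rho:.3f} below "
            f"{params.rank_correlation_min}",
            ConcordanceWarning,
            stacklevel=2,
        )
    cut_a = params.max_rank_fraction * size_a
    cut_b = params.max_rank_fraction * size_b
    for a, b in matching:
        if a.rank > cut_a or b.rank > cut_b:
            continue
        merged = GenomicInterval(a.chrom, min(a.start, b.start), max(a.end, b.end))
        repro = min(1 - a.rank / size_a, 1 - b.rank / size_b)
        result.peaks.append(
            ConsensusPeak(
                interval=merged,
                member_a=a,
                member_b=b,
                combined_score=(a.score + b.score) / 2.0,
                reproducibility=repro,
            )
        )
    return result


def consensus_peaks(
    rep_a: list[Peak], rep_b: list[Peak], params: ConsensusParams | None = None
) -> ConsensusResult:
    """Full simplified-reproducibility pipeline on a replicate pair."""
    params = params or ConsensusParams()
    matching = pair_replicates(rep_a, rep_b, params)
    return consensus_set(matching, len(rep_a), len(rep_b), params)


def consensus_as_peaks(result: ConsensusResult) -> list[Peak]:
    """Consensus peaks as plain :class:`Peak` objects (for downstream stages)."""
    out = []
    for i, cp in enumerate(sort_peaks_key(result.peaks)):
        out.append(
            Peak(cp.interval, name=f"consensus_{i + 1}", score=cp.combined_score)
        )
    from .genome import assign_ranks

    assign_ranks(out)
    return sort_peaks(out)


def sort_peaks_key(cpeaks: list[ConsensusPeak]) -> list[ConsensusPeak]:
    return sorted(cpeaks, key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end))
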
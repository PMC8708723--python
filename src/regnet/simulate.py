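"""Synthetic multi-TF ChIP-seq / RNA-seq fixtures with planted ground truth.

Emulates the data structure of a TF-in-ESC integrative study at desk
scale: a small genome with a TSS landscape, a cCRE catalog whose classes
are planted to be recoverable by the classifier, a target-TF peak set
with planted class proportions mirroring the promoter-heavy binding
profile (0.48 PLS / 0.134 pELS / 0.097 dELS), two replicates of the
target peak set, a panel of TFs in planted co-binding groups with
signal tracks, a planted TF -> gene edge table, NB count matrices with
planted DE genes and normalization factors, and genome sequence with a
planted IUPAC consensus motif in a configurable fraction of target peaks.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ccre import AssaySignals, CcreClass, CcreRecord
from .genome import (
    Genome,
    GenomicInterval,
    IntervalIndex,
    Peak,
    SignalTrack,
    TssRecord,
    ValidationError,
    assign_ranks,
    sort_peaks,
)
from .motifs import IupacMotif, sample_motif_instance

#: minimum spacing between planted TSSs; keeps basal regulatory domains
#: (5 kb + 1 kb) of neighboring genes disjoint with room for distal elements
MIN_TSS_GAP = 20_000
EDGE_MARGIN = 50_000

DEFAULT_CLASS_PROPORTIONS = {
    CcreClass.PLS: 0.48,
    CcreClass.PELS: 0.134,
    CcreClass.DELS: 0.097,
    CcreClass.DNASE_H3K4ME3: 0.10,
    CcreClass.DNASE_ONLY: 0.09,
}


@dataclass
class SimConfig:
    """All knobs of the generator; defaults are the study conditions."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 300
    # co-binding panel
    n_tfs: int = 13
    n_groups: int = 2
    within_group_corr: float = 0.8
    between_group_corr: float = 0.0
    n_regions: int = 1500
    region_width: int = 400
    peaks_per_tf: int = 500
    # target TF peaks / replicates
    n_target_peaks: int = 500
    peak_width: int = 300
    replicate_jitter_bp: int = 20
    replicate_dropout: float = 0.0
    class_proportions: Mapping[CcreClass, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    catalog_per_class: int = 300
    # network truth
    n_network_tfs: int = 8
    n_network_genes: int = 30
    edge_density: float = 0.3
    # counts
    n_samples_per_group: int = 4
    nb_dispersion: float = 0.1
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    low_expression_fraction: float = 0.10
    sample_factors: Sequence[float] | None = None
    # motif
    motif_consensus: str = "NCGGAAMM"
    motif_rate: float = 0.3

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if not all(0 <= p <= 1 for p in self.class_proportions.values()) or total > 1 + 1e-9:
            raise ValidationError("class proportions must lie in [0,1] and sum to <= 1")
        if self.n_groups < 1 or self.n_tfs < self.n_groups:
            raise ValidationError("need at least one TF per group")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class Annotation:
    genome: Genome
    tss: list[TssRecord]
    catalog: list[CcreRecord]


@dataclass
class CoBindingData:
    peak_sets: dict[str, list[Peak]]
    tracks: dict[str, SignalTrack]
    groups: dict[str, int]
    regions: list[GenomicInterval]


@dataclass
class NetworkTruth:
    peak_sets: dict[str, list[Peak]]
    peak_signals: dict[str, dict[str, AssaySignals]]
    edges: set[tuple[str, str]]
    tf_names: list[str]
    target_genes: list[str]


@dataclass
class CountData:
    counts: pd.DataFrame
    truth: pd.DataFrame  # gene, true_de in {up, down, ns}, true_log2fc
    true_factors: np.ndarray
    nominal_lib_sizes: np.ndarray
    groups: list[str]


def _spaced_positions(
    n: int, lo: int, hi: int, min_gap: int, rng: np.random.Generator
) -> np.ndarray:
    """n sorted positions in [lo, hi) pairwise >= min_gap apart."""
    span = hi - lo - (n - 1) * min_gap
    if span <= 0:
        raise ValidationError(
            f"genome too small for {n} features at spacing {min_gap}; "
            f"need at least {(n - 1) * min_gap + 2 * EDGE_MARGIN} bp"
        )
    raw = np.sort(rng.integers(0, span, size=n))
    return lo + raw + min_gap * np.arange(n)


def simulate_annotation(config: SimConfig, rng: np.random.Generator | None = None) -> Annotation:
    """Genome + TSS landscape + cCRE catalog with recoverable planted classes."""
    rng = rng or config.rng()
    chroms = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    genome = Genome(chroms)
    tss: list[TssRecord] = []
    per_chrom = np.array_split(np.arange(config.n_genes), config.n_chroms)
    gene_counter = 0
    for ci, chrom in enumerate(sorted(chroms)):
        n_here = len(per_chrom[ci])
        if n_here == 0:
            continue
        positions = _spaced_positions(
            n_here, EDGE_MARGIN, config.chrom_length - EDGE_MARGIN, MIN_TSS_GAP, rng
        )
        for pos in positions:
            gene_counter += 1
            strand = "+" if rng.random() < 0.5 else "-"
            tss.append(TssRecord(f"g{gene_counter:04d}", chrom, int(pos), strand))
    catalog: list[CcreRecord] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    def place(chrom: str, center: int, width: int) -> GenomicInterval | None:
        start, end = center - width // 2, center - width // 2 + width
        if start < 0 or end > chroms[chrom]:
            return None
        for s, e in occupied[chrom]:
            if start < e and s < end:
                return None
        occupied[chrom].append((start, end))
        return GenomicInterval(chrom, start, end)

    def planted_signals(cls: CcreClass) -> AssaySignals:
        jitter = lambda: float(rng.uniform(-0.3, 0.3))
        hi, lo = 3.0, -1.0
        if cls is CcreClass.PLS:
            return AssaySignals(hi + jitter(), hi + jitter(), lo + jitter())
        if cls in (CcreClass.PELS, CcreClass.DELS):
            return AssaySignals(hi + jitter(), lo + jitter(), hi + jitter())
        if cls is CcreClass.DNASE_H3K4ME3:
            return AssaySignals(hi + jitter(), hi + jitter(), lo + jitter())
        if cls is CcreClass.DNASE_ONLY:
            return AssaySignals(hi + jitter(), lo + jitter(), lo + jitter())
        return AssaySignals(lo + jitter(), lo + jitter(), lo + jitter())

    offset_ranges = {
        CcreClass.PLS: (0, 180),
        CcreClass.PELS: (350, 1800),
        CcreClass.DELS: (2500, 9000),
        CcreClass.DNASE_H3K4ME3: (2500, 9000),
        CcreClass.DNASE_ONLY: (2500, 9000),
    }
    width = 300
    for requested in (
        CcreClass.PLS,
        CcreClass.PELS,
        CcreClass.DELS,
        CcreClass.DNASE_H3K4ME3,
        CcreClass.DNASE_ONLY,
    ):
        # without any TSS, proximal classes cannot exist; their quota
        # becomes additional distal enhancer-like elements
        cls = requested
        if not tss and requested in (CcreClass.PLS, CcreClass.PELS):
            cls = CcreClass.DELS
        placed = 0
        attempts = 0
        lo_off, hi_off = offset_ranges[requested]
        while placed < config.catalog_per_class:
            attempts += 1
            if attempts > 50 * config.catalog_per_class:
                raise ValidationError(
                    f"could not place {config.catalog_per_class} {cls} elements; "
                    "genome too dense"
                )
            if tss:
                anchor = tss[int(rng.integers(len(tss)))]
                sign = -1 if rng.random() < 0.5 else 1
                offset = int(rng.integers(lo_off, hi_off + 1)) * sign
                center = anchor.position + offset
                chrom = anchor.chrom
            else:
                chrom = sorted(chroms)[int(rng.integers(len(chroms)))]
                center = int(rng.integers(EDGE_MARGIN, chroms[chrom] - EDGE_MARGIN))
            iv = place(chrom, center, width)
            if iv is None:
                continue
            catalog.append(CcreRecord(iv, planted_signals(cls), cls))
            placed += 1
    catalog.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return Annotation(genome=genome, tss=tss, catalog=catalog)


def _largest_remainder_counts(proportions: dict, n: int) -> dict:
    raw = {k: p * n for k, p in proportions.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    remainder = n - sum(counts.values())
    order = sorted(raw, key=lambda k: (-(raw[k] - counts[k]), str(k)))
    for k in order[:remainder]:
        counts[k] += 1
    return counts


def simulate_target_peaks(
    config: SimConfig, annotation: Annotation, rng: np.random.Generator | None = None
) -> tuple[list[Peak], dict[str, CcreClass]]:
    """Target-TF peak set with planted cCRE-class proportions.

    Peaks of planted class C sit exactly on a catalog element of class C;
    the remainder of the set is placed away from any catalog element
    (truth: unclassified).
    """
    rng = rng or config.rng()
    props = {CcreClass(k): v for k, v in dict(config.class_proportions).items()}
    props[CcreClass.UNCLASSIFIED] = 1.0 - sum(props.values())
    wanted = _largest_remainder_counts(props, config.n_target_peaks)
    by_class: dict[CcreClass, list[CcreRecord]] = {}
    for rec in annotation.catalog:
        by_class.setdefault(rec.ccre_class, []).append(rec)
    peaks: list[Peak] = []
    truth: dict[str, CcreClass] = {}
    counter = 0
    for cls, n_cls in wanted.items():
        if n_cls == 0:
            continue
        if cls is not CcreClass.UNCLASSIFIED:
            pool = by_class.get(cls, [])
            if len(pool) < n_cls:
                raise ValidationError(
                    f"catalog has only {len(pool)} {cls} elements, need {n_cls}"
                )
            chosen = rng.choice(len(pool), size=n_cls, replace=False)
            for idx in sorted(chosen):
                counter += 1
                iv = pool[int(idx)].interval
                name = f"target_pk{counter:04d}"
                peaks.append(
                    Peak(iv, name=name, score=float(rng.uniform(2, 10)),
                         summit_offset=iv.length // 2)
                )
                truth[name] = cls
        else:
            from .genome import IntervalIndex

            cat_index = IntervalIndex([r.interval for r in annotation.catalog])
            placed = 0
            while placed < n_cls:
                chrom = sorted(annotation.genome.chrom_sizes)[
                    int(rng.integers(config.n_chroms))
                ]
                center = int(
                    rng.integers(EDGE_MARGIN, annotation.genome.length_of(chrom) - EDGE_MARGIN)
                )
                iv = GenomicInterval(
                    chrom, center - config.peak_width // 2,
                    center - config.peak_width // 2 + config.peak_width,
                )
                if cat_index.query(iv):
                    continue
                if any(p.chrom == chrom and p.interval.overlaps(iv) for p in peaks):
                    continue
                counter += 1
                name = f"target_pk{counter:04d}"
                peaks.append(
                    Peak(iv, name=name, score=float(rng.uniform(2, 10)),
                         summit_offset=iv.length // 2)
                )
                truth[name] = CcreClass.UNCLASSIFIED
                placed += 1
    peaks = sort_peaks(peaks)
    assign_ranks(peaks)
    return peaks, truth


def simulate_replicate_pair(
    rng: np.random.Generator,
    genome: Genome,
    n_shared: int = 500,
    n_private: int = 250,
    peak_width: int = 300,
    jitter_bp: int = 20,
    dropout: float = 0.0,
) -> tuple[list[Peak], list[Peak], set[str]]:
    """Two replicate peak sets: planted shared peaks plus replicate-private ones.

    Shared peaks appear in both replicates with small positional jitter
    and correlated scores (each replicate loses a shared peak with
    probability ``dropout``); private peaks are placed disjoint from
    everything. Returns (rep_a, rep_b, names of peaks present in both).
    """
    chrom = sorted(genome.chrom_sizes)[0]
    total = n_shared + 2 * n_private
    centers = _spaced_positions(
        total, EDGE_MARGIN, genome.length_of(chrom) - EDGE_MARGIN,
        3 * peak_width + 2 * jitter_bp, rng,
    )
    rng.shuffle(centers)

    def mk(center: int, name: str, score: float) -> Peak:
        c = int(center + rng.integers(-jitter_bp, jitter_bp + 1))
        start = c - peak_width // 2
        return Peak(
            GenomicInterval(chrom, start, start + peak_width),
            name=name, score=score, summit_offset=peak_width // 2,
        )

    rep_a: list[Peak] = []
    rep_b: list[Peak] = []
    shared_names: set[str] = set()
    base_scores = rng.uniform(2, 10, size=total)
    for i in range(n_shared):
        name = f"shared{i + 1:04d}"
        in_a = dropout == 0 or rng.random() >= dropout
        in_b = dropout == 0 or rng.random() >= dropout
        if in_a:
            rep_a.append(mk(centers[i], name + "_a", base_scores[i] + rng.normal(0, 0.1)))
        if in_b:
            rep_b.append(mk(centers[i], name + "_b", base_scores[i] + rng.normal(0, 0.1)))
        if in_a and in_b:
            shared_names.add(name)
    for i in range(n_private):
        j = n_shared + i
        rep_a.append(mk(centers[j], f"privA{i + 1:04d}", base_scores[j]))
        k = n_shared + n_private + i
        rep_b.append(mk(centers[k], f"privB{i + 1:04d}", base_scores[k]))
    for rep in (rep_a, rep_b):
        rep.sort(key=lambda p: (p.chrom, p.start))
        assign_ranks(rep)
    return rep_a, rep_b, shared_names


def replicates_from_peaks(
    peaks: Sequence[Peak],
    rng: np.random.Generator,
    genome: Genome,
    n_private: int = 250,
    jitter_bp: int = 20,
    dropout: float = 0.0,
) -> tuple[list[Peak], list[Peak], set[str]]:
    """Two replicate realizations of a true peak set.

    Each replicate carries every true peak (minus dropout) at a jittered
    position with a correlated score, plus its own private noise peaks
    placed away from everything. Returns (rep_a, rep_b, names of true
    peaks present in both replicates).
    """
    if not peaks:
        return [], [], set()
    chrom = sorted(genome.chrom_sizes)[0]
    width = peaks[0].interval.length
    occupied = IntervalIndex([p.interval for p in peaks])

    def jittered(p: Peak, suffix: str) -> Peak:
        shift = int(rng.integers(-jitter_bp, jitter_bp + 1)) if jitter_bp else 0
        iv = GenomicInterval(p.chrom, p.start + shift, p.end + shift, p.interval.strand)
        return Peak(iv, name=p.name + suffix,
                    score=max(0.0, p.score + float(rng.normal(0, 0.1))),
                    summit_offset=p.summit_offset)

    rep_a: list[Peak] = []
    rep_b: list[Peak] = []
    shared: set[str] = set()
    for p in peaks:
        in_a = dropout == 0 or rng.random() >= dropout
        in_b = dropout == 0 or rng.random() >= dropout
        if in_a:
            rep_a.append(jittered(p, "_a"))
        if in_b:
            rep_b.append(jittered(p, "_b"))
        if in_a and in_b:
            shared.add(p.name)
    private_taken: list[GenomicInterval] = []  # across both replicates
    for rep, tag in ((rep_a, "A"), (rep_b, "B")):
        placed = 0
        guard = 0
        while placed < n_private:
            guard += 1
            if guard > 100 * n_private:
                raise ValidationError("could not place private replicate peaks")
            center = int(rng.integers(EDGE_MARGIN, genome.length_of(chrom) - EDGE_MARGIN))
            iv = GenomicInterval(chrom, center - width // 2, center - width // 2 + width)
            if occupied.query(iv):
                continue
            if any(t.chrom == chrom and t.overlaps(iv) for t in private_taken):
                continue
            placed += 1
            private_taken.append(iv)
            rep.append(Peak(iv, name=f"priv{tag}{placed:04d}",
                            score=float(rng.uniform(2, 10)),
                            summit_offset=width // 2))
        rep.sort(key=lambda p: (p.chrom, p.start))
        assign_ranks(rep)
    return rep_a, rep_b, shared


def simulate_cobinding(
    config: SimConfig, annotation: Annotation, rng: np.random.Generator | None = None
) -> CoBindingData:
    """TF panel with planted co-binding groups.

    Per region, each group draws a latent signal; a TF's log-signal is a
    mixture of its group latent (weight sqrt(within_group_corr)) and
    private noise, so factors of the same group correlate at about the
    configured level while factors of different groups are independent.
    Each TF's peak set is its top-scoring regions.
    """
    rng = rng or config.rng()
    chroms = sorted(annotation.genome.chrom_sizes)
    per_chrom = np.array_split(np.arange(config.n_regions), len(chroms))
    regions: list[GenomicInterval] = []
    for ci, chrom in enumerate(chroms):
        n_here = len(per_chrom[ci])
        if n_here == 0:
            continue
        starts = _spaced_positions(
            n_here, EDGE_MARGIN, annotation.genome.length_of(chrom) - EDGE_MARGIN,
            3 * config.region_width, rng,
        )
        regions.extend(
            GenomicInterval(chrom, int(s), int(s) + config.region_width) for s in starts
        )
    n_r = len(regions)
    tf_names = [f"TF{i + 1:02d}" for i in range(config.n_tfs)]
    groups = {tf: i % config.n_groups for i, tf in enumerate(tf_names)}
    latents = rng.normal(size=(config.n_groups, n_r))
    rho = config.within_group_corr
    peak_sets: dict[str, list[Peak]] = {}
    tracks: dict[str, SignalTrack] = {}
    for tf in tf_names:
        g = groups[tf]
        x = np.sqrt(rho) * latents[g] + np.sqrt(1 - rho) * rng.normal(size=n_r)
        signal = np.exp(0.5 * x)  # positive fold-enrichment-like values
        top = np.argsort(-x, kind="stable")[: config.peaks_per_tf]
        peaks = []
        for rank_pos, ri in enumerate(sorted(top)):
            peaks.append(
                Peak(regions[ri], name=f"{tf}_pk{rank_pos + 1:04d}",
                     score=float(signal[ri]))
            )
        peaks = sort_peaks(peaks)
        assign_ranks(peaks)
        peak_sets[tf] = peaks
        tracks[tf] = SignalTrack.from_records(
            (r.chrom, r.start, r.end, float(signal[i])) for i, r in enumerate(regions)
        )
    return CoBindingData(peak_sets=peak_sets, tracks=tracks, groups=groups, regions=regions)


def simulate_network(
    config: SimConfig,
    annotation: Annotation,
    rng: np.random.Generator | None = None,
    jitter_bp: int = 0,
) -> NetworkTruth:
    """Planted TF -> gene edge table realized as noiseless peak placement.

    Each network TF is named by the gene that encodes it (sampled from
    the annotation), so self-regulatory loops arise naturally. For every
    planted edge the TF gets one peak within 150 bp of the target TSS
    carrying high DNase/H3K4me3/H3K27ac signals; with ``jitter_bp`` the
    peak is displaced uniformly in [-jitter, +jitter].
    """
    rng = rng or config.rng()
    gene_ids = [t.gene_id for t in annotation.tss]
    n_pool = config.n_network_tfs + config.n_network_genes
    if n_pool > len(gene_ids):
        raise ValidationError("not enough genes for the requested network size")
    chosen = rng.choice(len(gene_ids), size=n_pool, replace=False)
    tf_genes = [gene_ids[int(i)] for i in chosen[: config.n_network_tfs]]
    target_genes = [gene_ids[int(i)] for i in chosen]  # TF genes are targets too
    tss_by_gene = {t.gene_id: t for t in annotation.tss}
    edges: set[tuple[str, str]] = set()
    peak_sets: dict[str, list[Peak]] = {tf: [] for tf in tf_genes}
    peak_signals: dict[str, dict[str, AssaySignals]] = {tf: {} for tf in tf_genes}
    for tf in tf_genes:
        counter = 0
        for gene in target_genes:
            if rng.random() >= config.edge_density:
                continue
            edges.add((tf, gene))
            counter += 1
            t = tss_by_gene[gene]
            offset = int(rng.integers(-150, 151))
            if jitter_bp:
                offset += int(rng.integers(-jitter_bp, jitter_bp + 1))
            center = t.position + offset
            start = max(0, center - config.peak_width // 2)
            iv = GenomicInterval(t.chrom, start, start + config.peak_width)
            name = f"{tf}_pk{counter:03d}"
            peak_sets[tf].append(Peak(iv, name=name, score=float(rng.uniform(2, 10))))
            peak_signals[tf][name] = AssaySignals(
                3.0 + float(rng.uniform(-0.3, 0.3)),
                3.0 + float(rng.uniform(-0.3, 0.3)),
                3.0 + float(rng.uniform(-0.3, 0.3)),
            )
        peak_sets[tf] = sort_peaks(peak_sets[tf])
        assign_ranks(peak_sets[tf])
    return NetworkTruth(
        peak_sets=peak_sets,
        peak_signals=peak_signals,
        edges=edges,
        tf_names=tf_genes,
        target_genes=target_genes,
    )


def simulate_counts(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    gene_ids: Sequence[str] | None = None,
    n_genes: int | None = None,
) -> CountData:
    """NB count matrix with planted DE genes and planted scaling factors.

    Two groups (control/knockdown) of ``n_samples_per_group`` samples.
    Planted per-sample factors multiply expected counts relative to the
    nominal library size (the expected column sum at factor 1), which is
    what :func:`regnet.expression.tmm_factors` recovers when given the
    nominal sizes.
    """
    rng = rng or config.rng()
    n = n_genes or (len(gene_ids) if gene_ids is not None else config.n_genes)
    genes = list(gene_ids) if gene_ids is not None else [f"g{i + 1:04d}" for i in range(n)]
    n_per = config.n_samples_per_group
    groups = ["control"] * n_per + ["knockdown"] * n_per
    samples = [f"ctrl_{i + 1}" for i in range(n_per)] + [f"kd_{i + 1}" for i in range(n_per)]
    factors = np.asarray(
        config.sample_factors if config.sample_factors is not None else np.ones(2 * n_per),
        dtype=float,
    )
    if len(factors) != 2 * n_per:
        raise ValidationError("sample_factors length must equal the sample count")
    # baseline means: mostly moderately expressed, a fraction near the filter floor
    mu = np.exp(rng.normal(np.log(100), 1.0, size=n))
    low = rng.random(n) < config.low_expression_fraction
    mu[low] = np.exp(rng.normal(np.log(0.5), 0.5, size=int(low.sum())))
    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    lfc = np.zeros(n)
    signs = np.where(rng.random(n_de) < 0.5, 1.0, -1.0)
    lfc[de_idx] = signs * config.de_log2fc
    phi = config.nb_dispersion
    mean_matrix = np.empty((n, 2 * n_per))
    for j in range(2 * n_per):
        fold = np.where(np.array(groups)[j] == "knockdown", 2.0 ** lfc, 1.0)
        mean_matrix[:, j] = mu * fold * factors[j]
    if phi > 0:
        p = 1.0 / (1.0 + phi * mean_matrix)
        counts = rng.negative_binomial(1.0 / phi, p)
    else:
        counts = rng.poisson(mean_matrix)
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    truth = pd.DataFrame(
        {
            "gene": genes,
            "true_log2fc": lfc,
            "true_de": ["up" if l > 0 else "down" if l < 0 else "ns" for l in lfc],
        }
    )
    nominal = np.array(
        [mu.sum() + (mu * (2.0 ** lfc - 1)).sum() * (g == "knockdown") for g in groups]
    )
    true_factors = factors / np.exp(np.mean(np.log(factors)))
    return CountData(
        counts=counts_df,
        truth=truth,
        true_factors=true_factors,
        nominal_lib_sizes=nominal,
        groups=groups,
    )


def simulate_tmm_fixture(
    rng: np.random.Generator,
    factors: Sequence[float] = (1.0, 1.5, 0.7),
    n_genes: int = 2000,
    dispersion: float = 0.1,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Single-condition NB counts with planted per-sample scaling factors.

    Returns (counts, nominal library sizes, true factors normalized to
    geometric mean 1). The planted factor multiplies expected counts
    relative to the nominal library size sum(mu).
    """
    factors = np.asarray(factors, dtype=float)
    mu = np.exp(rng.normal(np.log(100), 1.0, size=n_genes))
    mean_matrix = mu[:, None] * factors[None, :]
    if dispersion > 0:
        p = 1.0 / (1.0 + dispersion * mean_matrix)
        counts = rng.negative_binomial(1.0 / dispersion, p)
    else:
        counts = rng.poisson(mean_matrix)
    df = pd.DataFrame(
        counts,
        index=[f"g{i + 1:04d}" for i in range(n_genes)],
        columns=[f"s{j + 1}" for j in range(len(factors))],
    )
    nominal = np.full(len(factors), mu.sum())
    true = factors / np.exp(np.mean(np.log(factors)))
    return df, nominal, true


def simulate_sequences(
    config: SimConfig,
    annotation: Annotation,
    target_peaks: Sequence[Peak],
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], set[str]]:
    """Random genome sequence with the consensus motif planted in a
    fraction of target peaks (centered on the peak summit).

    Returns the sequences and the names of peaks that carry a planted
    instance.
    """
    rng = rng or config.rng()
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs: dict[str, bytearray] = {}
    for chrom in sorted(annotation.genome.chrom_sizes):
        n = annotation.genome.length_of(chrom)
        arr = alphabet[rng.integers(0, 4, size=n)]
        seqs[chrom] = bytearray(arr.tobytes())
    motif = IupacMotif(config.motif_consensus)
    planted: set[str] = set()
    for p in target_peaks:
        if rng.random() >= config.motif_rate:
            continue
        instance = sample_motif_instance(motif, rng)
        pos = p.center - len(instance) // 2
        if pos < 0 or pos + len(instance) > annotation.genome.length_of(p.chrom):
            continue
        seqs[p.chrom][pos : pos + len(instance)] = instance.encode()
        planted.add(p.name)
    return {c: s.decode() for c, s in seqs.items()}, planted


def write_dataset(config: SimConfig, outdir) -> dict:
    """Generate a full dataset and write every file the pipeline consumes.

    Emits chrom.sizes, TSS BED, classified cCRE BED (with z-score
    columns), two target-TF replicate narrowPeak files, per-panel-TF
    narrowPeak + bedGraph with a manifest, genome FASTA with planted
    motif instances, a counts TSV with sample groups, truth TSVs, and a
    ready-to-run ``run.yaml``. Returns a manifest of written paths.
    """
    from pathlib import Path

    import yaml

    from . import io as rio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    rng = config.rng()
    annotation = simulate_annotation(config, rng)
    target_peaks, target_truth = simulate_target_peaks(config, annotation, rng)
    rep_a, rep_b, shared = replicates_from_peaks(
        target_peaks,
        rng,
        annotation.genome,
        n_private=config.n_target_peaks // 2,
        jitter_bp=config.replicate_jitter_bp,
        dropout=config.replicate_dropout,
    )
    cobinding = simulate_cobinding(config, annotation, rng)
    counts = simulate_counts(config, rng)
    sequences, planted_names = simulate_sequences(config, annotation, target_peaks, rng)

    paths = {
        "chrom_sizes": out / "genome.chrom.sizes",
        "tss": out / "tss.bed",
        "ccre_catalog": out / "ccre.bed",
        "target_peaks": out / "target.narrowPeak",
        "replicate_a": out / "target_rep1.narrowPeak",
        "replicate_b": out / "target_rep2.narrowPeak",
        "genome_fasta": out / "genome.fa",
        "counts": out / "counts.tsv",
        "cooccupancy_manifest": out / "cooccupancy_manifest.tsv",
    }
    rio.write_chrom_sizes(annotation.genome, paths["chrom_sizes"])
    rio.write_tss_bed(annotation.tss, paths["tss"])
    rio.write_ccre_bed(
        (
            (r.interval, str(r.ccre_class),
             {"DNase": r.signals.dnase, "H3K4me3": r.signals.h3k4me3,
              "H3K27ac": r.signals.h3k27ac})
            for r in annotation.catalog
        ),
        paths["ccre_catalog"],
    )
    rio.write_peaks(target_peaks, paths["target_peaks"])
    rio.write_peaks(rep_a, paths["replicate_a"])
    rio.write_peaks(rep_b, paths["replicate_b"])
    rio.write_fasta(sequences, paths["genome_fasta"])
    counts.counts.rename_axis("gene").to_csv(paths["counts"], sep="\t")
    manifest_rows = []
    for tf in sorted(cobinding.peak_sets):
        pk = out / f"{tf}.narrowPeak"
        bg = out / f"{tf}.bedGraph"
        rio.write_peaks(cobinding.peak_sets[tf], pk)
        rio.write_bedgraph(cobinding.tracks[tf], bg)
        # paths relative to the manifest keep the dataset relocatable
        manifest_rows.append({"factor": tf, "peaks_path": pk.name, "track_path": bg.name})
    pd.DataFrame(manifest_rows).to_csv(paths["cooccupancy_manifest"], sep="\t", index=False)
    # ground truth for recovery checks
    pd.DataFrame(
        sorted(
            ({"peak_name": k, "true_class": str(v)} for k, v in target_truth.items()),
            key=lambda r: r["peak_name"],
        )
    ).to_csv(truth_dir / "target_peak_classes.tsv", sep="\t", index=False)
    pd.DataFrame({"shared_peak": sorted(shared)}).to_csv(
        truth_dir / "replicate_shared_peaks.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [{"factor": tf, "group": g} for tf, g in sorted(cobinding.groups.items())]
    ).to_csv(truth_dir / "cobinding_groups.tsv", sep="\t", index=False)
    counts.truth.to_csv(truth_dir / "de_truth.tsv", sep="\t", index=False)
    pd.DataFrame({"peak_name": sorted(planted_names)}).to_csv(
        truth_dir / "motif_planted_peaks.tsv", sep="\t", index=False
    )
    run_config = {
        "seed": config.seed,
        "output_dir": str(out / "pipeline_out"),
        "inputs": {
            "replicate_a": str(paths["replicate_a"]),
            "replicate_b": str(paths["replicate_b"]),
            "ccre_catalog": str(paths["ccre_catalog"]),
            "tss": str(paths["tss"]),
            "chrom_sizes": str(paths["chrom_sizes"]),
            "genome_fasta": str(paths["genome_fasta"]),
            "cooccupancy_manifest": str(paths["cooccupancy_manifest"]),
            "counts": str(paths["counts"]),
            "sample_groups": counts.groups,
        },
    }
    with open(out / "run.yaml", "w") as fh:
        yaml.safe_dump(run_config, fh, sort_keys=True)
    paths["run_config"] = out / "run.yaml"
    return {k: str(v) for k, v in paths.items()}


def random_sequences(
    n: int, length: int, rng: np.random.Generator, plant: str | None = None,
    plant_rate: float = 0.0,
) -> list[str]:
    """IID random ACGT sequences, optionally planting a motif instance."""
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    arr = alphabet[rng.integers(0, 4, size=(n, length))]
    seqs = [row.tobytes().decode() for row in arr]
    if plant and plant_rate > 0:
        motif = IupacMotif(plant)
        for i in range(n):
            if rng.random() < plant_rate:
                instance = sample_motif_instance(motif, rng)
                pos = int(rng.integers(0, length - len(instance) + 1))
                seqs[i] = seqs[i][:pos] + instance + seqs[i][pos + len(instance):]
    return seqs
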
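"""GREAT-style basal-plus-extension regulatory domains and peak-to-gene
association.

Each gene gets a basal domain (5 kb upstream to 1 kb downstream of its
canonical TSS, strand-aware) extended outward on each side up to 1 Mb but
stopping at the nearest neighboring gene's basal domain. A peak is
associated with every gene whose extended domain contains the peak center.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .genome import Genome, GenomicInterval, Peak, TssRecord, ValidationError


@dataclass
class DomainParams:
    """GREAT's published basal-plus-extension defaults."""

    upstream_bp: int = 5000
    downstream_bp: int = 1000
    max_extension_bp: int = 1_000_000

    def __post_init__(self) -> None:
        if min(self.upstream_bp, self.downstream_bp, self.max_extension_bp) <= 0:
            raise ValidationError("all domain parameters must be positive")


@dataclass
class RegulatoryDomain:
    gene_id: str
    tss: TssRecord
    basal: GenomicInterval
    extended: GenomicInterval


def _canonical_tss(tss_set: Sequence[TssRecord]) -> list[TssRecord]:
    """One TSS per gene: the first by genomic order."""
    by_gene: dict[str, TssRecord] = {}
    for t in sorted(tss_set, key=lambda t: (t.chrom, t.position, t.gene_id)):
        by_gene.setdefault(t.gene_id, t)
    return sorted(by_gene.values(), key=lambda t: (t.chrom, t.position, t.gene_id))


def build_regulatory_domains(
    tss_set: Sequence[TssRecord],
    genome: Genome,
    params: DomainParams | None = None,
) -> list[RegulatoryDomain]:
    params = params or DomainParams()
    canonical = _canonical_tss(tss_set)
    # basal domains first (needed as extension stops for every gene)
    basal: dict[str, GenomicInterval] = {}
    for t in canonical:
        chrom_len = genome.length_of(t.chrom)
        if t.position >= chrom_len:
            raise ValidationError(
                f"TSS of {t.gene_id} at {t.position} beyond chromosome "
                f"{t.chrom} length {chrom_len}"
            )
        if t.strand == "-":
            lo = t.position - params.downstream_bp + 1
            hi = t.position + params.upstream_bp + 1
        else:
            lo = t.position - params.upstream_bp
            hi = t.position + params.downstream_bp
        # clipping cannot empty the interval: lo <= position < chrom_len < hi or hi <= chrom_len
        basal[t.gene_id] = GenomicInterval(t.chrom, max(0, lo), min(chrom_len, hi))
    domains = []
    by_chrom: dict[str, list[TssRecord]] = {}
    for t in canonical:
        by_chrom.setdefault(t.chrom, []).append(t)
    for chrom, ts in by_chrom.items():
        chrom_len = genome.length_of(chrom)
        for i, t in enumerate(ts):
            b = basal[t.gene_id]
            left_limit = 0
            right_limit = chrom_len
            # nearest neighboring basal edges (genes are TSS-sorted per chrom)
            for j in range(i - 1, -1, -1):
                nb = basal[ts[j].gene_id]
                if nb.end <= b.start:
                    left_limit = nb.end
                    break
            for j in range(i + 1, len(ts)):
                nb = basal[ts[j].gene_id]
                if nb.start >= b.end:
                    right_limit = nb.start
                    break
            ext_start = max(b.start - params.max_extension_bp, left_limit)
            ext_end = min(b.end + params.max_extension_bp, right_limit)
            extended = GenomicInterval(
                chrom, min(ext_start, b.start), max(ext_end, b.end)
            )
            domains.append(RegulatoryDomain(t.gene_id, t, b, extended))
    domains.sort(key=lambda d: (d.basal.chrom, d.tss.position, d.gene_id))
    return domains


def associate_peaks(
    peaks: Sequence[Peak],
    domains: Sequence[RegulatoryDomain],
    whole_peak_overlap: bool = False,
) -> dict[str, set[str]]:
    """Map each peak (by name) to the genes whose domain contains it.

    Default rule: the peak *center* falls in the gene's extended domain.
    With ``whole_peak_overlap`` the peak associates with any gene whose
    extended domain shares >= 1 bp with it.
    """
    names = [p.name for p in peaks]
    if len(set(names)) != len(names):
        raise ValidationError("peak names must be unique for association")
    by_chrom: dict[str, list[RegulatoryDomain]] = {}
    for d in domains:
        by_chrom.setdefault(d.extended.chrom, []).append(d)
    out: dict[str, set[str]] = {}
    for p in peaks:
        genes: set[str] = set()
        for d in by_chrom.get(p.chrom, []):
            if whole_peak_overlap:
                hit = d.extended.overlaps(p.interval)
            else:
                hit = d.extended.start <= p.center < d.extended.end
            if hit:
                genes.add(d.gene_id)
        out[p.name] = genes
    return out


def association_table(
    peaks: Sequence[Peak],
    domains: Sequence[RegulatoryDomain],
    associations: Mapping[str, set[str]],
):
    """Flat rows (peak_name, gene_id, distance_to_tss) for export."""
    tss_by_gene = {d.gene_id: d.tss for d in domains}
    rows = []
    for p in peaks:
        for gene in sorted(associations.get(p.name, ())):
            t = tss_by_gene[gene]
            raw = p.center - t.position
            signed = -raw if t.strand == "-" else raw
            rows.append({"peak_name": p.name, "gene_id": gene, "distance_to_tss": signed})
    return rows
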
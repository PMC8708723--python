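"""Readers and writers for the plain-text formats the pipeline touches.

Supported dialects: BED6, ENCODE narrowPeak (10 columns), bedGraph,
2-column chrom.sizes, TSS BED (BED6 with the gene id in the name column),
simplified GTF (only ``gene`` records with a ``gene_id`` attribute), cCRE
BED (BED4+ with the class label in column 4 and optional DNase/H3K4me3/
H3K27ac z-score columns 5-7), and TSV tables via pandas.

All writers emit deterministic ordering (chrom, start, name). Internal
coordinates are 0-based half-open; GTF input (1-based inclusive) is
converted here at the boundary.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .genome import (
    Genome,
    GenomicInterval,
    Peak,
    SignalTrack,
    TssRecord,
    ValidationError,
    assign_ranks,
    sort_peaks,
)


class ParseError(ValueError):
    """A malformed line in a text format; carries file and line number."""

    def __init__(self, path, lineno: int, message: str) -> None:
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _data_lines(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_peaks(path, format: str = "narrowPeak") -> list[Peak]:
    """Read a peak file; peaks are returned sorted by (chrom, start).

    Ranks are taken as "assigned by descending score" when absent from the
    format (both BED6 and narrowPeak lack a rank column, so ranks are
    always recomputed from scores).
    """
    if format not in ("narrowPeak", "BED6"):
        raise ValueError(f"unknown peak format {format!r}")
    ncols = 10 if format == "narrowPeak" else 6
    peaks: list[Peak] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < ncols:
            raise ParseError(path, lineno, f"expected >= {ncols} columns, got {len(fields)}")
        chrom, start_s, end_s, name = fields[0], fields[1], fields[2], fields[3]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ParseError(path, lineno, "non-integer coordinates") from None
        if end <= start:
            raise ParseError(path, lineno, f"end {end} <= start {start}")
        strand = fields[5] if fields[5] in ("+", "-") else "."
        try:
            if format == "narrowPeak":
                score = float(fields[6])  # signalValue
                summit = int(fields[9])
                summit_offset = summit if summit >= 0 else None
            else:
                score = float(fields[4])
                summit_offset = None
        except ValueError:
            raise ParseError(path, lineno, "malformed numeric field") from None
        try:
            peaks.append(
                Peak(
                    GenomicInterval(chrom, start, end, strand),
                    name=name,
                    score=score,
                    summit_offset=summit_offset,
                )
            )
        except ValidationError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    peaks = sort_peaks(peaks)
    assign_ranks(peaks)
    return peaks


def write_peaks(peaks: Sequence[Peak], path, format: str = "narrowPeak") -> None:
    if format not in ("narrowPeak", "BED6"):
        raise ValueError(f"unknown peak format {format!r}")
    with open(path, "w") as fh:
        for p in sort_peaks(peaks):
            if format == "narrowPeak":
                summit = p.summit_offset if p.summit_offset is not None else -1
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t0\t{p.interval.strand}"
                    f"\t{p.score:g}\t-1\t-1\t{summit}\n"
                )
            else:
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score:g}"
                    f"\t{p.interval.strand}\n"
                )


def read_bedgraph(path) -> SignalTrack:
    records = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise ParseError(path, lineno, f"expected 4 columns, got {len(fields)}")
        try:
            records.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
        except ValueError:
            raise ParseError(path, lineno, "malformed bedGraph fields") from None
    try:
        return SignalTrack.from_records(records)
    except ValidationError as exc:
        raise ParseError(path, 0, str(exc)) from None


def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.records():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def read_chrom_sizes(path) -> Genome:
    sizes: dict[str, int] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise ParseError(path, lineno, "expected 2 columns")
        try:
            sizes[fields[0]] = int(fields[1])
        except ValueError:
            raise ParseError(path, lineno, "non-integer chromosome length") from None
    return Genome(sizes)


def write_chrom_sizes(genome: Genome, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome.chrom_sizes):
            fh.write(f"{chrom}\t{genome.chrom_sizes[chrom]}\n")


def read_tss_bed(path) -> list[TssRecord]:
    """BED6 of TSSs: the name column carries the gene id; start is the TSS."""
    out = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 6:
            raise ParseError(path, lineno, "expected 6 columns")
        try:
            start = int(fields[1])
        except ValueError:
            raise ParseError(path, lineno, "non-integer coordinate") from None
        strand = fields[5] if fields[5] in ("+", "-") else "."
        out.append(TssRecord(fields[3], fields[0], start, strand))
    return sorted(out, key=lambda t: (t.chrom, t.position, t.gene_id))


def write_tss_bed(tss_set: Iterable[TssRecord], path) -> None:
    with open(path, "w") as fh:
        for t in sorted(tss_set, key=lambda t: (t.chrom, t.position, t.gene_id)):
            fh.write(f"{t.chrom}\t{t.position}\t{t.position + 1}\t{t.gene_id}\t0\t{t.strand}\n")


_GTF_GENE_ID = re.compile(r'gene_id\s+"([^"]+)"')


def read_gtf_tss(path) -> list[TssRecord]:
    """Simplified GTF: only ``gene`` records with a gene_id attribute.

    GTF is 1-based inclusive; the TSS is the 5' end of the gene (start on
    '+', end on '-'), converted to a 0-based position.
    """
    out = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 9:
            raise ParseError(path, lineno, "expected 9 GTF columns")
        if fields[2] != "gene":
            continue
        m = _GTF_GENE_ID.search(fields[8])
        if not m:
            raise ParseError(path, lineno, "gene record without gene_id attribute")
        try:
            start1, end1 = int(fields[3]), int(fields[4])
        except ValueError:
            raise ParseError(path, lineno, "non-integer coordinates") from None
        strand = fields[6] if fields[6] in ("+", "-") else "."
        position = (start1 - 1) if strand != "-" else (end1 - 1)
        out.append(TssRecord(m.group(1), fields[0], position, strand))
    return sorted(out, key=lambda t: (t.chrom, t.position, t.gene_id))


def read_ccre_bed(path):
    """BED4+ cCRE catalog: class label in column 4, optional z-score columns.

    Columns 5-7, when present and numeric, are DNase / H3K4me3 / H3K27ac
    max-z scores. Returns a list of ``(GenomicInterval, class_label,
    signals_or_None)`` tuples; signals is a dict keyed by assay name.
    """
    out = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise ParseError(path, lineno, "expected >= 4 columns")
        try:
            iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
        except (ValueError, ValidationError) as exc:
            raise ParseError(path, lineno, str(exc)) from None
        signals = None
        if len(fields) >= 7:
            try:
                signals = {
                    "DNase": float(fields[4]),
                    "H3K4me3": float(fields[5]),
                    "H3K27ac": float(fields[6]),
                }
            except ValueError:
                signals = None
        out.append((iv, fields[3], signals))
    out.sort(key=lambda r: (r[0].chrom, r[0].start, r[0].end))
    return out


def write_ccre_bed(records, path) -> None:
    """Inverse of :func:`read_ccre_bed`."""
    rows = sorted(records, key=lambda r: (r[0].chrom, r[0].start, r[0].end))
    with open(path, "w") as fh:
        for iv, label, signals in rows:
            line = f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}"
            if signals is not None:
                line += (
                    f"\t{signals['DNase']:g}\t{signals['H3K4me3']:g}\t{signals['H3K27ac']:g}"
                )
            fh.write(line + "\n")


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_table(df: pd.DataFrame, path, index: bool = False, **kwargs) -> None:
    df.to_csv(path, sep="\t", index=index, **kwargs)


def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    """Small-FASTA reader returning plain uppercase strings."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is None:
                raise ParseError(path, 0, "sequence before FASTA header")
            else:
                seqs[name].append(line.upper())
    return {k: "".join(v) for k, v in seqs.items()}


def genome_from_fasta(fasta_path, chrom_sizes: dict[str, int] | None = None) -> Genome:
    """Genome with an indexed sequence accessor (pyfaidx)."""
    import pyfaidx

    fa = pyfaidx.Fasta(str(fasta_path))
    sizes = chrom_sizes or {name: len(fa[name]) for name in fa.keys()}
    return Genome(sizes, sequences=fa)


def peak_sequences(peaks: Sequence[Peak], genome: Genome, flank: int = 0) -> list[str]:
    """Sequences under peaks (optionally center +/- flank), clipped to the chromosome."""
    out = []
    for p in peaks:
        if flank:
            start = max(0, p.center - flank)
            end = min(genome.length_of(p.chrom), p.center + flank)
        else:
            start, end = p.start, p.end
        out.append(genome.fetch(p.chrom, start, end))
    return out
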
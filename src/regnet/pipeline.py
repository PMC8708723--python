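"""End-to-end orchestration: consensus -> cCRE annotation -> co-occupancy ->
peak-to-gene -> network -> expression integration -> motif enrichment.

Driven by a schema-validated YAML config; every stage logs its input and
output counts to a machine-readable run report so the analysis funnel
(peaks -> regulatory peaks -> bound genes -> DE-bound genes) is auditable.
Identical config + inputs yield byte-identical outputs (timing is logged,
never written into data files).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from . import io as rio
from .ccre import CcreClass, CcreParams, CcreRecord, AssaySignals, peakset_class_distribution
from .consensus import ConsensusParams, consensus_as_peaks, consensus_peaks
from .cooccupancy import build_merged_regions, jaccard_matrix, linkage_to_newick, score_matrix, spearman_cluster
from .domains import DomainParams, associate_peaks, association_table, build_regulatory_domains
from .expression import DEParams, bound_de_overlap, call_de, cpm, filter_low_expression, nb_exact_test, tmm_factors
from .genome import ValidationError
from .motifs import IupacMotif, enrichment_test
from .network import export_network, infer_edges, node_statistics, tf_panel_subgraph

logger = logging.getLogger("regnet")

ALL_STAGES = (
    "consensus",
    "annotate",
    "cooccupancy",
    "peak2gene",
    "network",
    "expression",
    "motif",
)


class ConsensusBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_reciprocal_overlap: float = 0.5
    rank_correlation_min: float = 0.5
    max_rank_fraction: float = 1.0


class CcreBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    tss_proximal_bp: int = 200
    els_proximal_bp: int = 2000
    high_z: float = 1.64
    low_z: float = 1.64


class DomainBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    upstream_bp: int = 5000
    downstream_bp: int = 1000
    max_extension_bp: int = 1_000_000


class DEBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    fdr_max: float = 0.05
    min_abs_log2fc: float = 0.2
    cpm_min: float = 1.0
    min_samples: int = 3


class InputsBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    replicate_a: Optional[str] = None
    replicate_b: Optional[str] = None
    ccre_catalog: Optional[str] = None
    tss: Optional[str] = None
    chrom_sizes: Optional[str] = None
    genome_fasta: Optional[str] = None
    cooccupancy_manifest: Optional[str] = None
    counts: Optional[str] = None
    sample_groups: Optional[list[str]] = None
    de_table: Optional[str] = None


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    output_dir: str = "regnet_out"
    stages: list[str] = Field(default_factory=lambda: list(ALL_STAGES))
    inputs: InputsBlock = Field(default_factory=InputsBlock)
    consensus: ConsensusBlock = Field(default_factory=ConsensusBlock)
    ccre: CcreBlock = Field(default_factory=CcreBlock)
    domains: DomainBlock = Field(default_factory=DomainBlock)
    de: DEBlock = Field(default_factory=DEBlock)
    motif_consensus: str = "NCGGAAMM"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)


def _require(value, name: str, stage: str):
    if value is None:
        raise ValidationError(f"stage {stage!r} requires input {name!r}")
    return value


def _read_catalog(path) -> list[CcreRecord]:
    records = []
    for iv, label, signals in rio.read_ccre_bed(path):
        sig = (
            AssaySignals(signals["DNase"], signals["H3K4me3"], signals["H3K27ac"])
            if signals
            else None
        )
        records.append(CcreRecord(iv, sig, CcreClass(label)))
    return records


#: file inputs each stage needs when upstream stages are not run
_STAGE_INPUTS = {
    "consensus": ("replicate_a", "replicate_b"),
    "annotate": ("ccre_catalog",),
    "cooccupancy": ("cooccupancy_manifest",),
    "peak2gene": ("tss", "chrom_sizes"),
    "network": ("ccre_catalog", "tss", "chrom_sizes", "cooccupancy_manifest"),
    "motif": ("genome_fasta",),
}


def validate_config(config: RunConfig) -> None:
    """Schema/path validation before any computation."""
    unknown = [s for s in config.stages if s not in ALL_STAGES]
    if unknown:
        raise ValidationError(f"unknown stage(s): {unknown}")
    for stage in config.stages:
        for field_name in _STAGE_INPUTS.get(stage, ()):
            value = getattr(config.inputs, field_name)
            if value is None:
                raise ValidationError(f"stage {stage!r} requires input {field_name!r}")
            if not Path(value).exists():
                raise ValidationError(
                    f"stage {stage!r}: input {field_name!r} path {value!r} does not exist"
                )
    if "expression" in config.stages:
        if config.inputs.de_table is None and (
            config.inputs.counts is None or config.inputs.sample_groups is None
        ):
            raise ValidationError(
                "stage 'expression' requires either de_table or counts + sample_groups"
            )


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages in order; returns the run report dict."""
    validate_config(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": config.model_dump(exclude={"inputs", "output_dir"}),
        "stages": {},
    }
    state: dict = {}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        try:
            stage_report = _STAGE_FUNCS[stage](config, state, out)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        elapsed = time.perf_counter() - t0
        logger.info("stage %s finished in %.2fs: %s", stage, elapsed, stage_report)
        report["stages"][stage] = stage_report
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report


def _stage_consensus(config: RunConfig, state: dict, out: Path) -> dict:
    inp = config.inputs
    rep_a = rio.read_peaks(_require(inp.replicate_a, "replicate_a", "consensus"))
    rep_b = rio.read_peaks(_require(inp.replicate_b, "replicate_b", "consensus"))
    params = ConsensusParams(**config.consensus.model_dump())
    result = consensus_peaks(rep_a, rep_b, params)
    peaks = consensus_as_peaks(result)
    state["consensus_peaks"] = peaks
    rio.write_peaks(peaks, out / "consensus.narrowPeak")
    pairs = pd.DataFrame(
        [
            {
                "name": cp.name,
                "rank_a": cp.member_a.rank,
                "rank_b": cp.member_b.rank,
                "combined_score": cp.combined_score,
                "reproducibility": cp.reproducibility,
            }
            for cp in result.peaks
        ]
    )
    rio.write_table(pairs, out / "consensus_pairs.tsv")
    return {
        "peaks_in": [len(rep_a), len(rep_b)],
        "peaks_out": len(peaks),
        "rank_correlation": round(result.rank_correlation, 6),
        "concordant": result.concordant,
    }


def _stage_annotate(config: RunConfig, state: dict, out: Path) -> dict:
    inp = config.inputs
    peaks = state.get("consensus_peaks")
    if peaks is None:
        peaks = rio.read_peaks(_require(inp.replicate_a, "replicate_a", "annotate"))
    catalog = _read_catalog(_require(inp.ccre_catalog, "ccre_catalog", "annotate"))
    classes, fractions = peakset_class_distribution(peaks, catalog)
    state["peak_classes"] = classes
    state["catalog"] = catalog
    per_peak = pd.DataFrame(
        sorted(
            ({"peak_name": k, "ccre_class": str(v)} for k, v in classes.items()),
            key=lambda r: r["peak_name"],
        )
    )
    rio.write_table(per_peak, out / "peak_classes.tsv")
    frac_df = pd.DataFrame(
        [{"ccre_class": str(c), "fraction": fractions[c]} for c in CcreClass]
    )
    rio.write_table(frac_df, out / "class_fractions.tsv")
    return {
        "peaks": len(peaks),
        "class_fractions": {str(c): round(f, 6) for c, f in fractions.items()},
    }


def _stage_cooccupancy(config: RunConfig, state: dict, out: Path) -> dict:
    inp = config.inputs
    manifest_path = Path(
        _require(inp.cooccupancy_manifest, "cooccupancy_manifest", "cooccupancy")
    )
    manifest = rio.read_table(manifest_path)
    peak_sets = {}
    tracks = {}
    for row in manifest.itertuples(index=False):
        # relative manifest entries resolve against the manifest location
        pk = manifest_path.parent / row.peaks_path
        bg = manifest_path.parent / row.track_path
        peak_sets[row.factor] = rio.read_peaks(pk)
        tracks[row.factor] = rio.read_bedgraph(bg)
    merged = build_merged_regions(peak_sets)
    scores = score_matrix(merged, tracks)
    result = spearman_cluster(scores)
    state["factor_peak_sets"] = peak_sets
    rio.write_table(scores.reset_index(names="factor"), out / "cooccupancy_scores.tsv")
    rio.write_table(
        result.correlation.reset_index(names="factor"), out / "spearman_correlation.tsv"
    )
    with open(out / "factor_dendrogram.nwk", "w") as fh:
        fh.write(linkage_to_newick(result.linkage, list(result.correlation.index)) + "\n")
    with open(out / "factor_leaf_order.txt", "w") as fh:
        fh.write("\n".join(result.leaf_order) + "\n")
    jac = jaccard_matrix(peak_sets)
    rio.write_table(jac.reset_index(names="factor"), out / "jaccard_overlap.tsv")
    return {
        "factors": len(peak_sets),
        "merged_regions": len(merged),
        "dropped_zero_regions": result.n_dropped_regions,
        "leaf_order": result.leaf_order,
    }


def _stage_peak2gene(config: RunConfig, state: dict, out: Path) -> dict:
    inp = config.inputs
    tss = rio.read_tss_bed(_require(inp.tss, "tss", "peak2gene"))
    genome = rio.read_chrom_sizes(_require(inp.chrom_sizes, "chrom_sizes", "peak2gene"))
    params = DomainParams(**config.domains.model_dump())
    domains = build_regulatory_domains(tss, genome, params)
    peaks = state.get("consensus_peaks")
    if peaks is None:
        peaks = rio.read_peaks(_require(inp.replicate_a, "replicate_a", "peak2gene"))
    assoc = associate_peaks(peaks, domains)
    state["domains"] = domains
    state["associations"] = assoc
    state["tss"] = tss
    rows = association_table(peaks, domains, assoc)
    classes = state.get("peak_classes", {})
    for r in rows:
        r["element_class"] = str(classes.get(r["peak_name"], ""))
    rio.write_table(
        pd.DataFrame(rows, columns=["peak_name", "gene_id", "distance_to_tss", "element_class"]),
        out / "peak_gene_associations.tsv",
    )
    bound = sorted({g for genes in assoc.values() for g in genes})
    promoter_bound = sorted(
        {
            g
            for pname, genes in assoc.items()
            if classes.get(pname) is CcreClass.PLS
            for g in genes
        }
    )
    state["bound_genes"] = bound
    state["promoter_bound_genes"] = promoter_bound
    state["gene_universe"] = sorted({t.gene_id for t in tss})
    return {
        "peaks": len(peaks),
        "genes_bound": len(bound),
        "promoter_bound_genes": len(promoter_bound),
    }


def _stage_network(config: RunConfig, state: dict, out: Path) -> dict:
    inp = config.inputs
    peak_sets = state.get("factor_peak_sets")
    if peak_sets is None:
        raise ValidationError("network stage requires the cooccupancy stage (factor peak sets)")
    catalog = state.get("catalog")
    if catalog is None:
        catalog = _read_catalog(_require(inp.ccre_catalog, "ccre_catalog", "network"))
    tss = state.get("tss") or rio.read_tss_bed(_require(inp.tss, "tss", "network"))
    genome = rio.read_chrom_sizes(_require(inp.chrom_sizes, "chrom_sizes", "network"))
    domains = state.get("domains") or build_regulatory_domains(
        tss, genome, DomainParams(**config.domains.model_dump())
    )
    from .ccre import assign_peak_classes

    classes = {f: assign_peak_classes(ps, catalog) for f, ps in peak_sets.items()}
    assoc = {f: associate_peaks(ps, domains) for f, ps in peak_sets.items()}
    network = infer_edges(peak_sets, classes, assoc)
    export_network(network, out / "network_edges.tsv")
    export_network(network, out / "network.graphml", format="graphml")
    rio.write_table(node_statistics(network), out / "node_degrees.tsv")
    panel = tf_panel_subgraph(network)
    export_network(panel, out / "network_tf_panel.tsv")
    return {
        "factors": len(peak_sets),
        "edges": len(network.edges),
        "tf_panel_edges": len(panel.edges),
    }


def _stage_expression(config: RunConfig, state: dict, out: Path) -> dict:
    inp = config.inputs
    params = DEParams(**config.de.model_dump())
    info: dict = {}
    if inp.de_table is not None:
        de_df = rio.read_table(inp.de_table)
    else:
        counts = rio.read_table(
            _require(inp.counts, "counts", "expression"), index_col=0
        )
        groups = _require(inp.sample_groups, "sample_groups", "expression")
        factors = tmm_factors(counts)
        cpm_df = cpm(counts, norm_factors=factors)
        retained = filter_low_expression(cpm_df, params)
        info["genes_in"] = int(counts.shape[0])
        info["genes_after_filter"] = int(len(retained))
        rio.write_table(
            pd.DataFrame({"sample": counts.columns, "tmm_factor": factors}),
            out / "tmm_factors.tsv",
        )
        pd.Series(retained, name="gene").to_csv(
            out / "retained_genes.tsv", sep="\t", index=False
        )
        de_df = nb_exact_test(counts.loc[retained], groups)
        rio.write_table(de_df, out / "de_table.tsv")
    up, down = call_de(de_df, params)
    info["n_up"] = len(up)
    info["n_down"] = len(down)
    pd.DataFrame(
        sorted(({"gene": g, "direction": "up"} for g in up), key=lambda r: r["gene"])
        + sorted(({"gene": g, "direction": "down"} for g in down), key=lambda r: r["gene"])
    ).to_csv(out / "de_genes.tsv", sep="\t", index=False)
    bound = state.get("promoter_bound_genes") or state.get("bound_genes")
    if bound:
        universe = state.get("gene_universe") or sorted(
            set(de_df["gene"] if "gene" in de_df.columns else de_df.index)
        )
        overlap = bound_de_overlap(bound, up, down, universe)
        overlap_rows = [
            {"metric": k, "value": json.dumps(v) if isinstance(v, list) else v}
            for k, v in sorted(overlap.items())
        ]
        rio.write_table(pd.DataFrame(overlap_rows), out / "bound_de_overlap.tsv")
        info["bound_down_fraction"] = round(overlap["bound_down_fraction"], 6)
    return info


def _stage_motif(config: RunConfig, state: dict, out: Path) -> dict:
    inp = config.inputs
    fasta = _require(inp.genome_fasta, "genome_fasta", "motif")
    genome = rio.genome_from_fasta(fasta)
    peaks = state.get("consensus_peaks")
    if peaks is None:
        peaks = rio.read_peaks(_require(inp.replicate_a, "replicate_a", "motif"))
    seqs = rio.peak_sequences(peaks, genome)
    motif = IupacMotif(config.motif_consensus)
    result = enrichment_test(motif, seqs, seed=config.seed)
    row = {
        "consensus": config.motif_consensus,
        "n_foreground": result.n_foreground,
        "k_foreground": result.k_foreground,
        "n_background": result.n_background,
        "k_background": result.k_background,
        "fold_enrichment": result.fold_enrichment,
        "pvalue": result.pvalue,
    }
    rio.write_table(pd.DataFrame([row]), out / "motif_enrichment.tsv")
    return {
        "foreground_fraction": round(result.foreground_fraction, 6),
        "background_fraction": round(result.background_fraction, 6),
        "fold_enrichment": round(result.fold_enrichment, 6)
        if np.isfinite(result.fold_enrichment)
        else "inf",
        "pvalue": result.pvalue,
    }


_STAGE_FUNCS = {
    "consensus": _stage_consensus,
    "annotate": _stage_annotate,
    "cooccupancy": _stage_cooccupancy,
    "peak2gene": _stage_peak2gene,
    "network": _stage_network,
    "expression": _stage_expression,
    "motif": _stage_motif,
}
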
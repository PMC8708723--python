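"""TF co-occupancy scoring and correlation clustering.

Co-occupancy scores are average (length-weighted mean) input-normalized
ChIP-seq signals of each factor over the merged set of genomic regions
bound by any factor in the panel. Factors are then clustered on the
pairwise Spearman correlation of their score vectors (distance 1 - rho,
average linkage by default). A Jaccard peak-overlap matrix is emitted as
a secondary binding-similarity statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .genome import GenomicInterval, IntervalIndex, Peak, SignalTrack, ValidationError, merge_intervals


@dataclass
class MergedRegionSet:
    """Disjoint merged regions plus which factors contributed peaks to each."""

    regions: list[GenomicInterval]
    provenance: list[frozenset[str]]  # parallel to regions

    def __len__(self) -> int:
        return len(self.regions)


@dataclass
class CooccupancyResult:
    scores: pd.DataFrame  # factors x regions
    correlation: pd.DataFrame  # factors x factors, Spearman
    linkage: np.ndarray
    leaf_order: list[str]
    n_dropped_regions: int = 0


def build_merged_regions(peak_sets: Mapping[str, Sequence[Peak]]) -> MergedRegionSet:
    """Merge the union of all factors' peaks; record per-region contributors."""
    if len(peak_sets) < 2:
        raise ValidationError("need >= 2 factors to build a merged region set")
    all_ivs = []
    for factor, peaks in peak_sets.items():
        if not peaks:
            warnings.warn(
                f"factor {factor!r} has an empty peak set; retained with zero "
                "contribution",
                stacklevel=2,
            )
        all_ivs.extend(p.interval for p in peaks)
    regions = merge_intervals(all_ivs)
    index = IntervalIndex(regions)
    contributors: list[set[str]] = [set() for _ in regions]
    pos = {iv: i for i, iv in enumerate(regions)}
    for factor, peaks in peak_sets.items():
        for p in peaks:
            for region, _ in index.query(p.interval):
                contributors[pos[region]].add(factor)
    return MergedRegionSet(regions, [frozenset(c) for c in contributors])


def score_matrix(
    regions: Sequence[GenomicInterval] | MergedRegionSet,
    tracks: Mapping[str, SignalTrack],
) -> pd.DataFrame:
    """Factors x regions matrix of length-weighted mean signal.

    Tracks are expected to be fold enrichment over input; bases without
    coverage count as signal 0.
    """
    if isinstance(regions, MergedRegionSet):
        regions = regions.regions
    cols = [f"{r.chrom}:{r.start}-{r.end}" for r in regions]
    data = {}
    for factor in sorted(tracks):
        track = tracks[factor]
        data[factor] = [track.mean_over(r.chrom, r.start, r.end) for r in regions]
    return pd.DataFrame.from_dict(data, orient="index", columns=cols)


def spearman_cluster(
    scores: pd.DataFrame, linkage_method: str = "average"
) -> CooccupancyResult:
    """Pairwise Spearman correlation of factors + hierarchical clustering.

    Regions with zero signal in every factor carry no rank information and
    are dropped (count reported). A factor with zero variance across the
    remaining regions gets correlation 0 to all others (with a warning).
    """
    if linkage_method not in ("average", "complete"):
        raise ValidationError("linkage_method must be 'average' or 'complete'")
    if scores.shape[0] < 2:
        raise ValidationError("need >= 2 factors")
    scores = scores.sort_index()  # deterministic factor order by name
    nonzero = (scores != 0).any(axis=0)
    n_dropped = int((~nonzero).sum())
    kept = scores.loc[:, nonzero]
    if kept.shape[1] < 3:
        raise ValidationError("need >= 3 informative regions")
    mat = kept.to_numpy(dtype=float)
    n = mat.shape[0]
    corr = np.eye(n)
    degenerate = [i for i in range(n) if np.std(mat[i]) == 0]
    if degenerate:
        warnings.warn(
            f"{len(degenerate)} factor(s) with zero signal variance; their "
            "correlations are set to 0",
            stacklevel=2,
        )
    for i in range(n):
        for j in range(i + 1, n):
            if i in degenerate or j in degenerate:
                rho = 0.0
            else:
                rho = float(stats.spearmanr(mat[i], mat[j]).statistic)
            corr[i, j] = corr[j, i] = rho
    corr_df = pd.DataFrame(corr, index=kept.index, columns=kept.index)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    leaves = hierarchy.leaves_list(Z)
    leaf_order = [kept.index[i] for i in leaves]
    return CooccupancyResult(
        scores=scores,
        correlation=corr_df,
        linkage=Z,
        leaf_order=leaf_order,
        n_dropped_regions=n_dropped,
    )


def cut_clusters(result: CooccupancyResult, k: int) -> dict[str, int]:
    """Cut the dendrogram into k flat clusters; factor name -> cluster id."""
    labels = hierarchy.fcluster(result.linkage, t=k, criterion="maxclust")
    return {f: int(c) for f, c in zip(result.correlation.index, labels)}


def jaccard_matrix(peak_sets: Mapping[str, Sequence[Peak]]) -> pd.DataFrame:
    """Secondary similarity: Jaccard index of merged-region occupancy."""
    merged = build_merged_regions(peak_sets)
    factors = sorted(peak_sets)
    occupancy = {
        f: np.array([f in prov for prov in merged.provenance]) for f in factors
    }
    n = len(factors)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = occupancy[factors[i]], occupancy[factors[j]]
            union = np.sum(a | b)
            out[i, j] = out[j, i] = float(np.sum(a & b) / union) if union else 0.0
    return pd.DataFrame(out, index=factors, columns=factors)


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Serialize a scipy linkage tree as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def render(node, parent_dist: float) -> str:
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return render(tree, tree.dist) + ";"
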
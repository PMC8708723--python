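"""Expression-side processing for ChIP/RNA integration.

Implements the edgeR-style preprocessing contract: CPM on normalized
library sizes, low-expression filtering (CPM >= 1 in >= 3 samples), TMM
normalization factors, Z-score scaling with Euclidean/complete-linkage
clustering of differentially expressed (DE) genes, DE-table thresholding
(FDR < 0.05 and |log2FC| > 0.2), and the bound-gene x DE-gene overlap
statistics with a hypergeometric enrichment test.

The DE statistics themselves are normally *consumed* from an external
table. For fully synthetic runs a simple two-group negative-binomial
exact-style test with a common moment-estimated dispersion and
Benjamini-Hochberg FDR is provided; it is a deliberately plain substitute
for a full quasi-likelihood GLM analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .genome import ValidationError


@dataclass
class DEParams:
    """Thresholds for DE calling and low-expression filtering."""

    fdr_max: float = 0.05
    min_abs_log2fc: float = 0.2
    cpm_min: float = 1.0
    min_samples: int = 3

    def __post_init__(self) -> None:
        if min(self.fdr_max, self.min_abs_log2fc, self.cpm_min, self.min_samples) <= 0:
            raise ValidationError("all DE parameters must be positive")


def _as_matrix(counts: pd.DataFrame) -> np.ndarray:
    mat = counts.to_numpy(dtype=float)
    if np.any(mat < 0):
        raise ValidationError("counts must be nonnegative")
    return mat


def cpm(
    counts: pd.DataFrame,
    norm_factors: np.ndarray | None = None,
    lib_sizes: np.ndarray | None = None,
) -> pd.DataFrame:
    """Counts per million on (optionally TMM-) normalized library sizes."""
    mat = _as_matrix(counts)
    if lib_sizes is None:
        lib_sizes = mat.sum(axis=0)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if np.any(lib_sizes <= 0):
        raise ValidationError("library sizes must be positive")
    if norm_factors is None:
        norm_factors = np.ones_like(lib_sizes)
    eff = lib_sizes * np.asarray(norm_factors, dtype=float)
    return pd.DataFrame(
        mat / eff * 1e6, index=counts.index, columns=counts.columns
    )


def filter_low_expression(cpm_matrix: pd.DataFrame, params: DEParams | None = None):
    """Genes with CPM >= cpm_min in >= min_samples samples."""
    params = params or DEParams()
    keep = (cpm_matrix >= params.cpm_min).sum(axis=1) >= params.min_samples
    retained = cpm_matrix.index[keep]
    if len(retained) == 0:
        warnings.warn("low-expression filter removed every gene", stacklevel=2)
    return retained


def _upper_quartile_reference(mat: np.ndarray, lib_sizes: np.ndarray) -> int:
    uq = np.array(
        [np.quantile(mat[:, j] / lib_sizes[j], 0.75) for j in range(mat.shape[1])]
    )
    return int(np.argmin(np.abs(uq - uq.mean())))


def tmm_factors(
    counts: pd.DataFrame,
    lib_sizes: np.ndarray | None = None,
    reference: int | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    For each sample against the reference (by default the sample whose
    count upper quartile is closest to the mean upper quartile), per-gene
    log ratios M and abundances A are computed on doubly-expressed genes;
    the top/bottom ``trim_m`` of M and ``trim_a`` of A are discarded and
    the factor is 2 to the precision-weighted mean of the surviving M.

    ``lib_sizes`` defaults to column sums; explicit (nominal) library
    sizes let the factor absorb depth differences deliberately planted
    relative to those nominal sizes.
    """
    mat = _as_matrix(counts)
    n_samples = mat.shape[1]
    if n_samples < 2:
        raise ValidationError("TMM needs >= 2 samples")
    if lib_sizes is None:
        lib_sizes = mat.sum(axis=0)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if reference is None:
        reference = _upper_quartile_reference(mat, lib_sizes)
    yr = mat[:, reference]
    nr = lib_sizes[reference]
    factors = np.ones(n_samples)
    for k in range(n_samples):
        if k == reference:
            continue
        yk = mat[:, k]
        nk = lib_sizes[k]
        expressed = (yk > 0) & (yr > 0)
        if not np.any(expressed):
            raise ValidationError(
                f"sample {counts.columns[k]!r} shares no expressed genes with the "
                "reference"
            )
        pk = yk[expressed] / nk
        pr = yr[expressed] / nr
        M = np.log2(pk / pr)
        A = 0.5 * np.log2(pk * pr)
        # asymptotic variance of M (delta method); weights are its inverse
        v = (nk - yk[expressed]) / (nk * yk[expressed]) + (nr - yr[expressed]) / (
            nr * yr[expressed]
        )
        n = len(M)
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        rank_m = stats.rankdata(M, method="ordinal")
        rank_a = stats.rankdata(A, method="ordinal")
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not np.any(keep):
            keep = np.ones(n, dtype=bool)
        with np.errstate(divide="ignore"):
            w = 1.0 / v[keep]
        f = np.sum(w * M[keep]) / np.sum(w)
        factors[k] = 2.0**f
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def zscore_cluster(cpm_matrix: pd.DataFrame, de_genes) -> dict:
    """Cluster DE genes and samples on Z-scored CPM.

    CPM values of each gene are scaled to mean 0 / sd 1 across samples;
    genes and samples are clustered with Euclidean distance and complete
    linkage. Zero-variance genes are dropped with a warning.
    """
    sub = cpm_matrix.loc[cpm_matrix.index.intersection(pd.Index(de_genes))]
    if sub.shape[1] < 2:
        raise ValidationError("Z-scores across samples need >= 2 samples")
    if sub.shape[0] < 2:
        raise ValidationError("need >= 2 DE genes to cluster")
    mat = sub.to_numpy(dtype=float)
    sd = mat.std(axis=1)
    keep = sd > 0
    if not np.all(keep):
        warnings.warn(f"dropped {int((~keep).sum())} zero-variance gene(s)", stacklevel=2)
    mat = mat[keep]
    genes = sub.index[keep]
    z = (mat - mat.mean(axis=1, keepdims=True)) / mat.std(axis=1, keepdims=True)
    gene_Z = hierarchy.linkage(z, method="complete", metric="euclidean")
    sample_Z = hierarchy.linkage(z.T, method="complete", metric="euclidean")
    return {
        "zscores": pd.DataFrame(z, index=genes, columns=sub.columns),
        "gene_linkage": gene_Z,
        "sample_linkage": sample_Z,
        "gene_order": [genes[i] for i in hierarchy.leaves_list(gene_Z)],
        "sample_order": [sub.columns[i] for i in hierarchy.leaves_list(sample_Z)],
    }


def call_de(de_table: pd.DataFrame, params: DEParams | None = None):
    """Threshold a DE table into disjoint up / down gene sets.

    Expects columns ``gene``, ``log2FC``, ``FDR`` (or a gene index).
    Up: FDR < fdr_max and log2FC > min_abs_log2fc; down: FDR < fdr_max
    and log2FC < -min_abs_log2fc.
    """
    params = params or DEParams()
    df = de_table
    if "gene" in df.columns:
        df = df.set_index("gene")
    for col in ("log2FC", "FDR"):
        if col not in df.columns:
            raise ValidationError(f"DE table missing required column {col!r}")
    if df["FDR"].min() < 0 or df["FDR"].max() > 1:
        raise ValidationError("FDR values must lie in [0, 1]")
    sig = df["FDR"] < params.fdr_max
    up = df.index[sig & (df["log2FC"] > params.min_abs_log2fc)]
    down = df.index[sig & (df["log2FC"] < -params.min_abs_log2fc)]
    return set(up), set(down)


def estimate_common_dispersion(adjusted: np.ndarray, groups: np.ndarray) -> float:
    """Moment estimator of a common NB dispersion across genes.

    Uses E[s^2] = m + phi m^2 within each group, pooled over genes as a
    ratio estimator; clipped at 0.
    """
    num = 0.0
    den = 0.0
    for g in np.unique(groups):
        sub = adjusted[:, groups == g]
        if sub.shape[1] < 2:
            continue
        m = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        ok = m > 0
        num += float(np.sum(s2[ok] - m[ok]))
        den += float(np.sum(m[ok] ** 2))
    if den == 0:
        return 0.0
    return max(0.0, num / den)


def _exact_nb_pvalue(s_a: int, s_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Conditional two-sided exact-style test on group count sums.

    Conditions on the total s = s_a + s_b; under the null both group sums
    are NB with shared per-sample mean and sizes n/phi. The p-value is
    the summed probability of all splits as or less likely than the one
    observed (edgeR's doubletail convention). phi -> 0 degenerates to the
    conditional binomial.
    """
    s = s_a + s_b
    if s == 0:
        return 1.0
    k = np.arange(s + 1)
    if phi < 1e-8:
        logp = stats.binom.logpmf(k, s, n_b / (n_a + n_b))
    else:
        mu = s / (n_a + n_b)
        size_a, size_b = n_a / phi, n_b / phi
        p_a = size_a / (size_a + n_a * mu)
        p_b = size_b / (size_b + n_b * mu)
        logp = stats.nbinom.logpmf(s - k, size_a, p_a) + stats.nbinom.logpmf(
            k, size_b, p_b
        )
    logp = logp - logsumexp(logp)
    p_obs = logp[s_b]
    return float(min(1.0, np.exp(logsumexp(logp[logp <= p_obs + 1e-12]))))


def nb_exact_test(
    counts: pd.DataFrame,
    groups,
    norm_factors: np.ndarray | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Two-group NB exact-style DE test with common dispersion + BH FDR.

    ``groups`` is a length-n_samples sequence with exactly two levels;
    the second level (sorted) is treated as the treatment for the sign of
    log2FC. Counts are scaled to a common effective library size before
    summing within groups (a quantile-free simplification).
    """
    groups = np.asarray(groups)
    levels = sorted(set(groups.tolist()))
    if len(levels) != 2:
        raise ValidationError("nb_exact_test needs exactly two groups")
    mat = _as_matrix(counts)
    lib = mat.sum(axis=0)
    if norm_factors is None:
        norm_factors = tmm_factors(counts)
    eff = lib * norm_factors
    common = float(np.exp(np.mean(np.log(eff))))
    adjusted = mat * (common / eff)
    phi = estimate_common_dispersion(adjusted, groups)
    ctrl, treat = levels[0], levels[1]
    a_cols = groups == ctrl
    b_cols = groups == treat
    n_a, n_b = int(a_cols.sum()), int(b_cols.sum())
    s_a = np.rint(adjusted[:, a_cols].sum(axis=1)).astype(np.int64)
    s_b = np.rint(adjusted[:, b_cols].sum(axis=1)).astype(np.int64)
    pvals = np.array(
        [_exact_nb_pvalue(int(a), int(b), n_a, n_b, phi) for a, b in zip(s_a, s_b)]
    )
    log2fc = np.log2((s_b / n_b + prior_count) / (s_a / n_a + prior_count))
    fdr = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {"gene": counts.index, "log2FC": log2fc, "PValue": pvals, "FDR": fdr}
    )


def bound_de_overlap(
    bound_genes, up_genes, down_genes, universe
) -> dict:
    """Overlap of TF-bound genes with DE sets, plus hypergeometric enrichment.

    Reports |bound & down| / |bound| (the headline "bound and
    down-modulated" fraction), the same for up, 2x2 contingency tables
    against the gene universe, and one-sided hypergeometric p-values for
    over-representation of bound genes among each DE set.
    """
    universe = set(universe)
    bound = set(bound_genes) & universe
    if not bound:
        raise ValidationError("bound gene set is empty (within the universe)")
    out = {"n_bound": len(bound), "n_universe": len(universe)}
    for label, de in (("down", set(down_genes) & universe), ("up", set(up_genes) & universe)):
        k = len(bound & de)
        M, K, n = len(universe), len(de), len(bound)
        out[f"n_{label}"] = len(de)
        out[f"n_bound_{label}"] = k
        out[f"bound_{label}_fraction"] = k / len(bound)
        out[f"p_hypergeom_{label}"] = float(stats.hypergeom.sf(k - 1, M, K, n))
        out[f"table_{label}"] = [
            [k, n - k],
            [K - k, M - K - (n - k)],
        ]
    return out
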
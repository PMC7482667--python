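"""Label-free quantitative statistics.

The processing chain mirrors standard LFQ practice: confidence filter on
unique-peptide counts (>=2), total-intensity normalization on the linear
scale, log2 transform, left-censored (down-shifted Gaussian) imputation of
missing values, then a one-way ANOVA screen across all groups and Welch
pairwise t-tests with Benjamini-Hochberg correction.  A volcano rule
(|log2 fold change| >= 1.2 and p < 0.05) classifies proteins as UP, DOWN
or NS.  Ward clustering and PCA summarize sample structure, and a
Delta-Delta-Ct fold change supports the RT-qPCR arm.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .io import AbundanceMatrix, check_metadata

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Pre-processing
# ---------------------------------------------------------------------------

def filter_by_unique_peptides(matrix: AbundanceMatrix, min_peptides: int = 2) -> AbundanceMatrix:
    """Keep proteins identified by at least ``min_peptides`` unique peptides.

    Protein order is preserved.  Raises when no counts are attached, so a
    caller who wants no filtering must skip this step explicitly.
    """
    counts = matrix.unique_peptide_counts
    if counts is None:
        raise ValueError(
            "no unique-peptide counts attached to this matrix; either attach "
            "counts or skip the peptide filter explicitly"
        )
    keep = counts[counts >= min_peptides].index
    kept = matrix.values.loc[matrix.values.index.intersection(keep, sort=False)]
    # intersection preserves left (matrix) order
    out = AbundanceMatrix(
        kept, scale=matrix.scale, unique_peptide_counts=counts.reindex(kept.index)
    )
    logger.info(
        "peptide filter (>=%d): kept %d of %d proteins",
        min_peptides, len(out.protein_ids), len(matrix.protein_ids),
    )
    return out


def normalize_total_intensity(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Scale each sample so its observed intensity total equals the grand
    mean of all samples' totals (linear scale only; masked cells untouched).

    Conserves the grand total of observed intensity."""
    if matrix.scale != "linear":
        raise ValueError("total-intensity normalization requires a linear-scale matrix")
    totals = matrix.values.sum(axis=0, skipna=True)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero observed total intensity: {list(zero.index)}")
    factors = totals.mean() / totals
    return matrix.copy_with(matrix.values * factors, scale="linear")


def log2_transform(matrix: AbundanceMatrix) -> AbundanceMatrix:
    if matrix.scale != "linear":
        raise ValueError("matrix is already on the log2 scale")
    return matrix.copy_with(np.log2(matrix.values), scale="log2")


def delog2_transform(matrix: AbundanceMatrix) -> AbundanceMatrix:
    if matrix.scale != "log2":
        raise ValueError("matrix is not on the log2 scale")
    return matrix.copy_with(2.0 ** matrix.values, scale="linear")


def impute_missing(
    matrix: AbundanceMatrix,
    shift: float = 1.8,
    width: float = 0.3,
    seed: int = 0,
) -> AbundanceMatrix:
    """Left-censored imputation on the log2 scale.

    Each missing entry is drawn from Normal(sample mean - shift*sample SD,
    width*sample SD), the down-shifted Gaussian that models intensities too
    low for consistent detection.  Deterministic under ``seed``; samples
    are processed in column order.
    """
    if matrix.scale != "log2":
        raise ValueError("imputation operates on the log2 scale")
    rng = np.random.default_rng(seed)
    values = matrix.values.copy()
    for sample in values.columns:
        col = values[sample]
        observed = col.dropna()
        if len(observed) < 2:
            raise ValueError(
                f"sample {sample!r} has {len(observed)} observed values; "
                "need >= 2 to estimate an imputation distribution"
            )
        n_missing = int(col.isna().sum())
        if n_missing == 0:
            continue
        mu = float(observed.mean())
        sd = float(observed.std(ddof=1))
        draws = rng.normal(mu - shift * sd, width * sd, size=n_missing)
        values.loc[col.isna(), sample] = draws
    return matrix.copy_with(values, scale="log2")


# ---------------------------------------------------------------------------
# Differential abundance
# ---------------------------------------------------------------------------

def bh_adjust(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order and length preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _group_arrays(
    matrix: AbundanceMatrix, metadata: pd.Series, groups: list[str] | None = None
) -> dict[str, np.ndarray]:
    check_metadata(matrix, metadata)
    labels = metadata.reindex(matrix.sample_ids)
    if groups is None:
        groups = sorted(labels.unique())
    arrays = {}
    for g in groups:
        cols = labels.index[labels == g]
        if len(cols) == 0:
            raise ValueError(f"unknown or empty group label: {g!r}")
        arrays[g] = matrix.values.loc[:, cols].to_numpy()
    return arrays


def anova_screen(
    matrix: AbundanceMatrix, metadata: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """One-way fixed-effects F-test per protein across all groups.

    Requires a complete (imputed) matrix and at least two groups of at
    least two samples.  Proteins with zero variance everywhere are flagged
    ``degenerate`` and reported with p = 1 rather than raising, so screens
    on synthetic edge cases always complete.  BH q-values are computed over
    the tested set; ``significant`` flags p <= alpha.
    """
    if not matrix.is_complete():
        raise ValueError("ANOVA screen requires a complete (imputed) matrix")
    arrays = _group_arrays(matrix, metadata)
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for g, arr in arrays.items():
        if arr.shape[1] < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_stat, p = sps.f_oneway(*arrays.values(), axis=1)
    degenerate = ~np.isfinite(p)
    p = np.where(degenerate, 1.0, p)
    f_stat = np.where(np.isfinite(f_stat), f_stat, 0.0)
    result = pd.DataFrame(
        {
            "protein": matrix.protein_ids,
            "test": "anova",
            "statistic": f_stat,
            "p_value": p,
            "q_value": bh_adjust(p),
            "significant": p <= alpha,
            "degenerate": degenerate,
        }
    )
    for g, arr in arrays.items():
        result[f"mean_{g}"] = arr.mean(axis=1)
    return result


def ttest_pair(
    matrix: AbundanceMatrix,
    metadata: pd.Series,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch two-sample t-test per protein for group_a vs group_b.

    log2_fc = mean(group_a) - mean(group_b) on the log2 scale.  Degenerate
    proteins (zero variance and equal means) report t = 0, p = 1.
    """
    if not matrix.is_complete():
        raise ValueError("t-test requires a complete (imputed) matrix")
    arrays = _group_arrays(matrix, metadata, [group_a, group_b])
    a, b = arrays[group_a], arrays[group_b]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("both groups need >= 2 samples")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t_stat, p = sps.ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = ~np.isfinite(p)
    p = np.where(degenerate, 1.0, p)
    t_stat = np.where(np.isfinite(t_stat), t_stat, 0.0)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    return pd.DataFrame(
        {
            "protein": matrix.protein_ids,
            "test": f"welch_t:{group_a}_vs_{group_b}",
            "statistic": t_stat,
            "p_value": p,
            "q_value": bh_adjust(p),
            "log2_fc": mean_a - mean_b,
            f"mean_{group_a}": mean_a,
            f"mean_{group_b}": mean_b,
            "significant": p <= alpha,
            "degenerate": degenerate,
        }
    )


def classify_volcano(
    de_results: pd.DataFrame, fc_cut: float = 1.2, p_cut: float = 0.05
) -> pd.DataFrame:
    """Volcano classification: UP iff log2_fc >= fc_cut and p < p_cut
    (boundary fold change counts as UP), DOWN symmetric, otherwise NS."""
    if "log2_fc" not in de_results or "p_value" not in de_results:
        raise ValueError("de_results must carry log2_fc and p_value columns")
    fc = de_results["log2_fc"].to_numpy()
    p = de_results["p_value"].to_numpy()
    cls = np.where(
        (fc >= fc_cut) & (p < p_cut),
        "UP",
        np.where((fc <= -fc_cut) & (p < p_cut), "DOWN", "NS"),
    )
    out = de_results[["protein", "log2_fc", "p_value"]].copy()
    out["volcano_class"] = cls
    out["fc_cut"] = fc_cut
    out["p_cut"] = p_cut
    return out


# ---------------------------------------------------------------------------
# Sample-structure summaries
# ---------------------------------------------------------------------------

def ward_cluster(matrix: AbundanceMatrix, k: int) -> pd.Series:
    """Agglomerative Ward clustering of samples on Euclidean distances,
    cut at k clusters.  Returns sample -> cluster label (1..k)."""
    if not matrix.is_complete():
        raise ValueError("clustering requires a complete matrix")
    n_samples = len(matrix.sample_ids)
    if not 1 <= k <= n_samples:
        raise ValueError(f"k must be in 1..{n_samples}, got {k}")
    X = matrix.values.to_numpy().T  # samples x proteins
    Z = linkage(X, method="ward", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=matrix.sample_ids, name="cluster")


def pca_scores(
    matrix: AbundanceMatrix, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on centered protein abundances.

    Returns (scores, explained_variance_ratio); components are ordered by
    explained variance."""
    if not matrix.is_complete():
        raise ValueError("PCA requires a complete matrix")
    X = matrix.values.to_numpy().T
    max_comp = min(X.shape)
    if not 1 <= n_components <= max_comp:
        raise ValueError(f"n_components must be in 1..{max_comp}")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    df = pd.DataFrame(
        scores,
        index=matrix.sample_ids,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return df, pca.explained_variance_ratio_


# ---------------------------------------------------------------------------
# RT-qPCR fold change
# ---------------------------------------------------------------------------

def ddct_fold_change(
    ct_target_trt: float,
    ct_ref_trt: float,
    ct_target_ctl: float,
    ct_ref_ctl: float,
) -> float:
    """Delta-Delta-Ct fold change 2^-[(Ct_t,trt - Ct_ref,trt) - (Ct_t,ctl - Ct_ref,ctl)].

    Reference Ct values are means over the housekeeping-gene panel."""
    for name, ct in {
        "ct_target_trt": ct_target_trt,
        "ct_ref_trt": ct_ref_trt,
        "ct_target_ctl": ct_target_ctl,
        "ct_ref_ctl": ct_ref_ctl,
    }.items():
        if not np.isfinite(ct):
            raise ValueError(f"{name} must be finite, got {ct}")
    ddct = (ct_target_trt - ct_ref_trt) - (ct_target_ctl - ct_ref_ctl)
    return float(2.0 ** -ddct)


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

def run_stats_pipeline(
    matrix: AbundanceMatrix,
    metadata: pd.Series,
    contrast: tuple[str, str] | None = None,
    alpha: float = 0.05,
    fc_cut: float = 1.2,
    min_peptides: int | None = 2,
    impute_shift: float = 1.8,
    impute_width: float = 0.3,
    seed: int = 0,
    normalize_before_impute: bool = True,
) -> dict:
    """Run the fixed processing chain and the statistical screens.

    Default order: peptide filter -> total-intensity normalization -> log2
    -> imputation -> tests.  ``normalize_before_impute=False`` imputes (on
    log2 of the raw matrix) first and normalizes afterwards (on the
    back-transformed linear values), for users who prefer that reading of
    the processing order.  Every step and parameter is logged.
    """
    params = dict(
        alpha=alpha, fc_cut=fc_cut, min_peptides=min_peptides,
        impute_shift=impute_shift, impute_width=impute_width, seed=seed,
        normalize_before_impute=normalize_before_impute,
        contrast=contrast,
    )
    logger.info("stats pipeline parameters: %s", params)
    steps: list[str] = []
    m = matrix
    if min_peptides is not None and m.unique_peptide_counts is not None:
        m = filter_by_unique_peptides(m, min_peptides)
        steps.append(f"peptide_filter(min={min_peptides})")
    if normalize_before_impute:
        m = normalize_total_intensity(m)
        steps.append("normalize_total_intensity")
        m = log2_transform(m)
        steps.append("log2")
        m = impute_missing(m, shift=impute_shift, width=impute_width, seed=seed)
        steps.append(f"impute(shift={impute_shift},width={impute_width},seed={seed})")
    else:
        m = log2_transform(m)
        steps.append("log2")
        m = impute_missing(m, shift=impute_shift, width=impute_width, seed=seed)
        steps.append(f"impute(shift={impute_shift},width={impute_width},seed={seed})")
        m = normalize_total_intensity(delog2_transform(m))
        steps.append("normalize_total_intensity")
        m = log2_transform(m)
        steps.append("log2")
    logger.info("stats pipeline order: %s", " -> ".join(steps))
    out: dict = {"matrix": m, "steps": steps, "params": params}
    out["anova"] = anova_screen(m, metadata, alpha=alpha)
    if contrast is not None:
        tt = ttest_pair(m, metadata, contrast[0], contrast[1], alpha=alpha)
        out["ttest"] = tt
        out["volcano"] = classify_volcano(tt, fc_cut=fc_cut, p_cut=alpha)
    n_samples = len(m.sample_ids)
    n_groups = metadata.reindex(m.sample_ids).nunique()
    out["clusters"] = ward_cluster(m, k=min(n_groups, n_samples))
    out["pca"], out["pca_explained_variance_ratio"] = pca_scores(
        m, n_components=min(2, min(len(m.protein_ids), n_samples))
    )
    return out
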
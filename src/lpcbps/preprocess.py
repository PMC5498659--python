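"""Normalization, variance filtering and per-process PCA mapping spaces.

Tumor expression is centered and scaled per gene against the reference
(normal) samples; without references, a per-gene z-score is used instead.
Low-variance genes are removed, and each gene set's expression is embedded
into the subspace of its leading principal components whose tumor-sample
variance exceeds the normal-sample variance by a configured margin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.decomposition import PCA

from .io import ExpressionMatrix, PipelineError

logger = logging.getLogger(__name__)


@dataclass
class MappingSpace:
    """Per-process PCA embedding in which the principal curve is fitted.

    ``scores`` are the mean-centered projections of ALL samples (tumor and
    normal) onto the first ``k`` components; ``loadings`` has orthonormal
    columns.
    """

    process_name: str
    scores: np.ndarray  # (n_samples, k)
    loadings: np.ndarray  # (n_genes_in_set, k)
    component_variances_tumor: np.ndarray  # (k,)
    component_variances_normal: Optional[np.ndarray]  # (k,) or None
    k: int


def normalize_vs_reference(
    expr: ExpressionMatrix, scale: str = "variance"
) -> ExpressionMatrix:
    """Center and scale each gene against the reference samples.

    With references: value[g, s] <- (value[g, s] - mean_ref(g)) / var_ref(g)
    for every sample (``scale='sd'`` divides by the standard deviation
    instead).  Genes with zero reference variance are dropped with a warning
    (the division is undefined).  Without references, each gene is z-scored
    across all samples; the variance estimator is unbiased (n-1) throughout.
    """
    if scale not in ("variance", "sd"):
        raise ValueError("scale must be 'variance' or 'sd'")
    values = expr.values
    if expr.is_reference.any():
        ref = values[:, expr.is_reference]
        if ref.shape[1] < 2:
            raise ValueError(
                "need at least 2 reference samples to estimate reference variance"
            )
        mean = ref.mean(axis=1)
        var = ref.var(axis=1, ddof=1)
        keep = var > 0
        dropped = int((~keep).sum())
        if dropped:
            logger.warning(
                "dropped %d genes with zero reference variance", dropped
            )
        if not keep.any():
            raise PipelineError("every gene has zero reference variance")
        denom = var[keep] if scale == "variance" else np.sqrt(var[keep])
        out = (values[keep] - mean[keep, None]) / denom[:, None]
        genes = [g for g, k in zip(expr.gene_ids, keep) if k]
    else:
        mean = values.mean(axis=1)
        sd = values.std(axis=1, ddof=1)
        keep = sd > 0
        dropped = int((~keep).sum())
        if dropped:
            logger.warning("dropped %d constant genes (zero variance)", dropped)
        if not keep.any():
            raise PipelineError("every gene is constant")
        out = (values[keep] - mean[keep, None]) / sd[keep, None]
        genes = [g for g, k in zip(expr.gene_ids, keep) if k]
    return ExpressionMatrix(out, genes, expr.sample_ids, expr.is_reference)


def filter_low_variance(
    expr: ExpressionMatrix, quantile: float = 0.25
) -> ExpressionMatrix:
    """Remove genes whose variance is strictly below the given variance quantile.

    The threshold is the order statistic ``sorted_variances[floor(quantile*G)]``,
    so with all-distinct variances exactly ``floor(quantile*G)`` genes are
    removed; ties at the threshold survive (strict comparison).
    """
    if expr.n_samples < 2:
        raise ValueError("need at least 2 samples to estimate variances")
    if not 0.0 <= quantile < 1.0:
        raise ValueError("quantile must be in [0, 1)")
    variances = expr.values.var(axis=1, ddof=1)
    idx = int(np.floor(quantile * len(variances)))
    idx = min(idx, len(variances) - 1)
    threshold = np.sort(variances)[idx]
    keep = variances >= threshold
    if not keep.any():
        raise PipelineError("variance filter removed every gene")
    removed = int((~keep).sum())
    if removed:
        logger.info("variance filter removed %d / %d genes", removed, len(variances))
    genes = [g for g, k in zip(expr.gene_ids, keep) if k]
    return ExpressionMatrix(
        expr.values[keep], genes, expr.sample_ids, expr.is_reference
    )


def build_mapping_space(
    expr_subset: ExpressionMatrix,
    geneset_name: str,
    excess_fraction: float = 0.10,
    component_rule: str = "contiguous",
    component_compare: str = "total",
    explained_variance_fallback: float = 0.80,
    max_components: int = 4,
) -> MappingSpace:
    """Fit PCA on one gene set's normalized expression over all samples.

    The retained dimension k counts the leading components whose tumor-score
    variance exceeds the normal samples' variance by more than
    ``excess_fraction``.  Under the default ``component_compare='total'`` a
    component qualifies when its tumor variance exceeds ``excess_fraction``
    times the normals' TOTAL variance; ``'per_component'`` compares against
    ``(1 + excess_fraction)`` times the normal variance along that same
    component.  Components are scanned in decreasing-eigenvalue order,
    stopping at the first failure under the default "contiguous" rule
    ("count_all" counts every qualifying component); k is floored at 1.
    Without usable normal samples the rule degenerates and k becomes the
    smallest number of components explaining at least
    ``explained_variance_fallback`` of the total variance.

    ``max_components`` caps k: trailing components carry mostly sampling
    noise, and the kernel-weighted curve search degrades quickly with
    dimension (the effective neighborhood shrinks by ~2.7x per added
    dimension at the default bandwidths), so redundant components are
    omitted for curve stability.
    """
    if expr_subset.n_genes < 2:
        raise PipelineError(
            f"gene set {geneset_name!r} has {expr_subset.n_genes} genes in the "
            "expression matrix; need >= 2"
        )
    if expr_subset.n_samples < 3:
        raise ValueError("need at least 3 samples")

    X = expr_subset.values.T  # samples x genes
    n_comp = min(expr_subset.n_genes, expr_subset.n_samples - 1)
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # genes x components, orthonormal columns

    tumor = ~expr_subset.is_reference
    normal = expr_subset.is_reference
    v_tumor = scores[tumor].var(axis=0, ddof=1) if tumor.sum() >= 2 else scores.var(
        axis=0, ddof=1
    )

    if normal.sum() >= 2:
        v_normal = scores[normal].var(axis=0, ddof=1)
        if component_compare == "total":
            qualifies = v_tumor > excess_fraction * v_normal.sum()
        elif component_compare == "per_component":
            qualifies = v_tumor > (1.0 + excess_fraction) * v_normal
        else:
            raise ValueError(f"unknown component_compare {component_compare!r}")
        if component_rule == "contiguous":
            k = int(np.argmin(qualifies)) if not qualifies.all() else len(qualifies)
        elif component_rule == "count_all":
            k = int(qualifies.sum())
        else:
            raise ValueError(f"unknown component_rule {component_rule!r}")
        k = max(k, 1)
    else:
        v_normal = None
        cum = np.cumsum(pca.explained_variance_ratio_)
        k = int(np.searchsorted(cum, explained_variance_fallback) + 1)
        k = min(k, n_comp)
        logger.info(
            "%s: no normal samples; k=%d from %.0f%% explained-variance fallback",
            geneset_name, k, 100 * explained_variance_fallback,
        )
    k = min(k, max_components)

    return MappingSpace(
        process_name=geneset_name,
        scores=scores[:, :k],
        loadings=loadings[:, :k],
        component_variances_tumor=v_tumor[:k],
        component_variances_normal=None if v_normal is None else v_normal[:k],
        k=k,
    )
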
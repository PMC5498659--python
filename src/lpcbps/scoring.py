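"""Per-process scoring: mapping space -> LPC -> parameterized curve ->
projection indices -> normalized Biological Process Scores (BPS).

For each gene set, samples are embedded into the set's PCA mapping space, a
local principal curve is grown from the reference centroid (or the density
mode when no reference samples exist), the curve is arc-length parameterized
with its origin anchored at the starting point's projection, and every
sample's signed projection index is normalized into [0, 1].  A BPS of 0 sits
at the reference origin end of the observed index range, 1 at the far end.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Tuple

import numpy as np

from .config import Config
from .curve import build_curve, project_points, set_origin
from .io import BPSMatrix, ExpressionMatrix, GeneSetCollection, PipelineError
from .lpc import choose_start, default_bandwidth, fit_lpc
from .preprocess import build_mapping_space, filter_low_variance, normalize_vs_reference

logger = logging.getLogger(__name__)


def normalize_indices(t: np.ndarray, mode: str = "minmax") -> np.ndarray:
    """Map projection indices into [0, 1].

    ``minmax``: (t - min) / (max - min).  ``clamp_minmax``: negative indices
    (samples projecting behind the reference origin) are clamped to 0 first,
    then divided by the maximum, preserving the origin's semantics.  Constant
    vectors map to all zeros.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("projection indices must be finite")
    if mode == "minmax":
        span = t.max() - t.min()
        if span == 0:
            return np.zeros_like(t)
        return (t - t.min()) / span
    if mode == "clamp_minmax":
        clamped = np.clip(t, 0.0, None)
        top = clamped.max()
        if top == 0:
            return np.zeros_like(clamped)
        return clamped / top
    raise ValueError(f"unknown normalization mode {mode!r}")


def score_embedding(
    scores: np.ndarray,
    reference_rows: Optional[Sequence[int]] = None,
    config: Optional[Config] = None,
) -> Tuple[np.ndarray, dict]:
    """Run LPC -> curve -> projection on an existing embedding.

    Returns raw (un-normalized) signed projection indices for every row of
    ``scores`` plus fit metadata.  The scoring origin is the reference
    centroid when reference rows are given, otherwise the mean-shift mode.
    """
    cfg = config or Config()
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    bw = default_bandwidth(scores, cfg.bandwidth_fraction)
    has_refs = reference_rows is not None and len(reference_rows) > 0
    x0 = choose_start(scores, reference_rows if has_refs else None, bw)
    two_sided = cfg.two_sided if cfg.two_sided is not None else not has_refs
    path = fit_lpc(
        scores,
        x0,
        bw,
        step=cfg.step_size,
        tol=cfg.tol,
        max_iter=cfg.max_iter,
        angle_penalty=cfg.angle_penalty,
        two_sided=two_sided,
        boundary_frac=cfg.boundary_frac,
    )
    curve = build_curve(
        path.centers,
        grid_per_interval=cfg.grid_per_interval,
        extension_fraction=cfg.extension_fraction,
    )
    curve = set_origin(curve, x0)
    t, dist = project_points(curve, scores, refine=cfg.projection_refine)
    meta = {
        "L": len(path.centers),
        "stop_reason": dict(path.stop_reason),
        "two_sided": two_sided,
        "mean_projection_distance": float(dist.mean()),
    }
    return t, meta


def score_process(
    expr: ExpressionMatrix,
    name: str,
    genes: Sequence[str],
    config: Optional[Config] = None,
) -> Tuple[np.ndarray, dict]:
    """Score one gene set on an already normalized+filtered expression matrix.

    Returns (bps, metadata).  Raises PipelineError when the set cannot be
    scored (too few genes present, or no local structure at the start).
    """
    cfg = config or Config()
    if cfg.case_insensitive:
        lookup = {}
        for g in expr.gene_ids:  # first occurrence wins
            lookup.setdefault(g.lower(), g)
        present = [lookup[g.lower()] for g in genes if g.lower() in lookup]
    else:
        available = set(expr.gene_ids)
        present = [g for g in genes if g in available]
    if len(present) < cfg.min_genes_per_set:
        raise PipelineError(
            f"gene set {name!r}: {len(present)} of {len(genes)} genes present, "
            f"need >= {cfg.min_genes_per_set}"
        )
    subset = expr.subset_genes(present)
    space = build_mapping_space(
        subset,
        name,
        excess_fraction=cfg.pc_excess_fraction,
        component_rule=cfg.component_rule,
        component_compare=cfg.component_compare,
        explained_variance_fallback=cfg.explained_variance_fallback,
        max_components=cfg.max_components,
    )
    reference_rows = np.flatnonzero(expr.is_reference)
    try:
        t, meta = score_embedding(
            space.scores,
            reference_rows if reference_rows.size else None,
            cfg,
        )
    except ValueError as exc:
        raise PipelineError(f"gene set {name!r}: {exc}") from exc
    constant = bool(t.max() == t.min())
    bps = normalize_indices(t, cfg.normalization)
    meta.update(
        k=space.k,
        genes_used=len(present),
        constant=constant,
        normalization=cfg.normalization,
    )
    return bps, meta


def score_all(
    expr: ExpressionMatrix,
    genesets: GeneSetCollection,
    config: Optional[Config] = None,
) -> BPSMatrix:
    """Preprocess once, then score every gene set independently.

    The expression matrix is normalized against the reference samples (or
    z-scored without them) and variance-filtered before any set is scored.
    Unsalvageable sets are skipped with their reason recorded.
    """
    cfg = config or Config()
    normalized = normalize_vs_reference(expr, scale=cfg.scale)
    filtered = filter_low_variance(normalized, quantile=cfg.variance_filter_quantile)

    rows = []
    names = []
    metadata = {}
    skipped = {}
    for name in genesets.names:
        try:
            bps, meta = score_process(filtered, name, genesets.genes(name), cfg)
        except PipelineError as exc:
            logger.warning("skipping %s: %s", name, exc)
            skipped[name] = str(exc)
            continue
        rows.append(bps)
        names.append(name)
        metadata[name] = meta
    if not rows:
        raise PipelineError(
            "no gene set could be scored; reasons: " + "; ".join(
                f"{k}: {v}" for k, v in skipped.items()
            )
        )
    return BPSMatrix(
        values=np.vstack(rows),
        process_names=names,
        sample_ids=expr.sample_ids,
        metadata=metadata,
        skipped=skipped,
    )
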
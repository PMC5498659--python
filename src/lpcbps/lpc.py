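"""Local principal curve fitting by bottom-up kernel-weighted traversal.

Starting from a point x0 (the centroid of the reference samples, or the
density mode found by mean shift), the algorithm alternates three steps:

1. localized center of mass  mu^x = sum_i w_i X_i  with Gaussian kernel
   weights  w_i = K_H(X_i - x) / sum_j K_H(X_j - x);
2. first eigenvector gamma^x of the local weighted covariance
   sigma_jk = sum_i w_i (X_ij - mu_j)(X_ik - mu_k), with its sign chosen for
   continuity with the previous direction;
3. a step of fixed size t0 along gamma^x:  x <- mu^x + t0 * gamma^x.

The traversal stops when the center of mass converges, the boundary of the
data cloud is reached (kernel mass drops below a fraction of the densest
point visited), or an iteration cap is hit.  The ordered centers of mass form
the local principal curve.  H = diag(h_1^2, ..., h_p^2) with h_j defaulting
to 10% of the data range in each dimension.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))


class EmptyNeighborhoodError(RuntimeError):
    """Every kernel value underflowed: x is outside the data cloud."""


class DegenerateDirectionError(RuntimeError):
    """The local weighted covariance has no positive leading eigenvalue."""


@dataclass
class Bandwidth:
    """Diagonal Gaussian kernel bandwidth: H = diag(h_1^2, ..., h_p^2)."""

    h: np.ndarray

    def __post_init__(self) -> None:
        self.h = np.atleast_1d(np.asarray(self.h, dtype=float))
        if not np.all(self.h > 0):
            raise ValueError("all bandwidths must be positive")

    @property
    def mean(self) -> float:
        return float(self.h.mean())

    @property
    def max(self) -> float:
        return float(self.h.max())


@dataclass
class LPCPath:
    """Ordered local centers of mass forming the fitted curve."""

    centers: np.ndarray  # (L, p)
    start_point: np.ndarray
    step_size: float
    stop_reason: Dict[str, str]  # per traversal direction
    directions: int  # 1 or 2 merged traversals

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if len(self.centers) < 2:
            raise ValueError("an LPC path needs at least 2 centers")


def default_bandwidth(scores: np.ndarray, fraction: float = 0.10) -> Bandwidth:
    """Per-dimension bandwidth: ``fraction`` of the data range in that dimension.

    A dimension with zero range falls back to ``fraction`` times the pooled
    standard deviation over all dimensions, with a warning.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] < 2:
        raise ValueError("need at least 2 points")
    ranges = scores.max(axis=0) - scores.min(axis=0)
    h = fraction * ranges
    degenerate = ranges <= 0
    if degenerate.any():
        pooled_sd = float(scores.std())
        if pooled_sd <= 0:
            raise ValueError("all points identical; bandwidth undefined")
        logger.warning(
            "%d dimension(s) with zero range; using fraction * pooled SD",
            int(degenerate.sum()),
        )
        h[degenerate] = fraction * pooled_sd
    return Bandwidth(h)


def _log_kernel(x: np.ndarray, scores: np.ndarray, bw: Bandwidth) -> np.ndarray:
    """log K_H(X_i - x) for every data point, K the standard Gaussian density."""
    z = (scores - x) / bw.h
    p = scores.shape[1]
    return (
        -0.5 * np.einsum("ij,ij->i", z, z)
        - np.log(bw.h).sum()
        - 0.5 * p * _LOG_2PI
    )


def kernel_mass(x: np.ndarray, scores: np.ndarray, bw: Bandwidth) -> float:
    """Unnormalized kernel mass sum_i K_H(X_i - x); the boundary statistic."""
    return float(np.exp(_log_kernel(np.asarray(x, float), scores, bw)).sum())


def kernel_weights(x: np.ndarray, scores: np.ndarray, bw: Bandwidth) -> np.ndarray:
    """Normalized Gaussian kernel weights at x; sums to 1.

    Raises EmptyNeighborhoodError when every kernel value underflows to zero.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    raw = np.exp(_log_kernel(np.asarray(x, dtype=float), scores, bw))
    total = raw.sum()
    if total == 0.0:
        raise EmptyNeighborhoodError("all kernel values underflowed at x")
    return raw / total


def local_center_of_mass(
    x: np.ndarray, scores: np.ndarray, bw: Bandwidth
) -> np.ndarray:
    """mu^x = sum_i w_i X_i; a convex combination of the data points."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    return kernel_weights(x, scores, bw) @ scores


def local_first_eigenvector(
    x: np.ndarray,
    scores: np.ndarray,
    bw: Bandwidth,
    mu: Optional[np.ndarray] = None,
    prev_dir: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Unit top eigenvector of the local weighted covariance at x.

    The sign is flipped so that dot(gamma, prev_dir) >= 0 when a previous
    direction is given; otherwise the first nonzero coordinate is made
    positive (deterministic).
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    w = kernel_weights(x, scores, bw)
    if mu is None:
        mu = w @ scores
    centered = scores - mu
    cov = (w[:, None] * centered).T @ centered
    if not np.all(np.isfinite(cov)):
        raise DegenerateDirectionError("non-finite local covariance")
    eigvals, eigvecs = np.linalg.eigh(cov)
    if eigvals[-1] <= 0:
        raise DegenerateDirectionError("local covariance has no positive eigenvalue")
    gamma = eigvecs[:, -1]
    gamma = gamma / np.linalg.norm(gamma)
    if prev_dir is not None:
        if float(gamma @ prev_dir) < 0:
            gamma = -gamma
    else:
        nz = np.flatnonzero(np.abs(gamma) > 1e-12)
        if nz.size and gamma[nz[0]] < 0:
            gamma = -gamma
    return gamma


def _directional_step(gamma: np.ndarray, bw: Bandwidth) -> float:
    """One bandwidth in the kernel metric along gamma.

    Equals h_j for travel along axis j; shrinks for directions with
    components in narrow (low-variance) dimensions, so a step never jumps
    many bandwidths in any single dimension.
    """
    return float(1.0 / np.linalg.norm(gamma / bw.h))


def _traverse(
    scores: np.ndarray,
    x0: np.ndarray,
    bw: Bandwidth,
    init_dir: np.ndarray,
    step: Optional[float],
    tol: float,
    max_iter: int,
    angle_penalty: float,
    boundary_frac: float,
    boundary_ref: float,
) -> tuple:
    centers = []
    cum = [0.0]  # path length walked up to each recorded center
    x = np.asarray(x0, dtype=float).copy()
    prev_dir = init_dir
    mu_prev = None
    stop = "max_iter"
    dt = step if step is not None else _directional_step(init_dir, bw)
    for _ in range(max_iter):
        try:
            w = kernel_weights(x, scores, bw)
        except EmptyNeighborhoodError:
            stop = "boundary"
            break
        mu = w @ scores
        # self-crossing guard: a center landing on a part of the path at
        # least two steps behind (along the walked length) means the
        # traversal U-turned at the data boundary and is re-walking the
        # curve, which would fold the parameterization
        if centers:
            walked = cum[-1] + float(np.linalg.norm(mu - centers[-1]))
            behind = walked - np.asarray(cum) > 2.0 * dt
            if behind.any():
                back = np.linalg.norm(np.asarray(centers)[behind] - mu, axis=1)
                if back.min() < 0.5 * dt:
                    stop = "boundary"
                    break
            cum.append(walked)
        centers.append(mu)
        if mu_prev is not None and np.linalg.norm(mu - mu_prev) < tol:
            stop = "converged"
            break
        mu_prev = mu
        try:
            gamma = local_first_eigenvector(x, scores, bw, mu, prev_dir)
        except DegenerateDirectionError:
            stop = "boundary"
            break
        if angle_penalty < 1.0 and prev_dir is not None:
            blend = angle_penalty * gamma + (1.0 - angle_penalty) * prev_dir
            norm = np.linalg.norm(blend)
            if norm > 0:
                gamma = blend / norm
        prev_dir = gamma
        dt = step if step is not None else _directional_step(gamma, bw)
        x = mu + dt * gamma
        if kernel_mass(x, scores, bw) < boundary_frac * boundary_ref:
            stop = "boundary"
            break
    # prune the stall tail: as the traversal converges against the data
    # boundary it records a cluster of nearly coincident centers whose jitter
    # would corrupt the spline's end tangent; keep only the final one
    if len(centers) >= 2:
        final = centers[-1]
        j = len(centers) - 2
        while j >= 0 and np.linalg.norm(centers[j] - final) < 0.5 * dt:
            j -= 1
        centers = centers[: j + 1] + [final]
    return centers, stop


def fit_lpc(
    scores: np.ndarray,
    x0: np.ndarray,
    bw: Bandwidth,
    step: Optional[float] = None,
    tol: Optional[float] = None,
    max_iter: Optional[int] = None,
    angle_penalty: float = 1.0,
    two_sided: bool = False,
    boundary_frac: float = 0.01,
) -> LPCPath:
    """Fit a local principal curve through ``scores`` starting at ``x0``.

    With ``two_sided`` a second traversal starts from x0 along the negated
    initial eigenvector and is prepended in reverse, so the path covers both
    sides of the starting point.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    n = scores.shape[0]
    # default step (step=None): one bandwidth in the kernel metric along the
    # current direction — h_j for axis-aligned travel, smaller for directions
    # with components in narrow dimensions.  A fixed mean(h) step is dragged
    # down by low-variance dimensions and cannot escape a dense reference
    # cluster; a fixed max(h) step overshoots by many bandwidths when the
    # direction leaves the widest dimension.
    if step is not None and float(step) <= 0:
        raise ValueError("step size must be positive")
    step = None if step is None else float(step)
    tol = 1e-3 * bw.mean if tol is None else float(tol)
    max_iter = 10 * n if max_iter is None else int(max_iter)

    try:
        w0 = kernel_weights(x0, scores, bw)
        mu0 = w0 @ scores
        gamma0 = local_first_eigenvector(x0, scores, bw, mu0)
    except (EmptyNeighborhoodError, DegenerateDirectionError) as exc:
        raise ValueError(f"no local structure at starting point: {exc}") from exc
    # point the (sign-ambiguous) initial direction into the data cloud, so a
    # one-sided traversal from a boundary start (e.g. the normal centroid)
    # grows through the data rather than stalling at the nearby edge
    inward = scores.mean(axis=0) - x0
    if float(gamma0 @ inward) < 0:
        gamma0 = -gamma0

    # boundary reference: the typical (median) kernel mass at the data points
    # themselves.  Referencing the densest visited point instead would abort
    # traversals that start inside a dense reference-sample cluster, whose
    # mass can exceed the interior's by orders of magnitude.
    boundary_ref = float(
        np.median([kernel_mass(xi, scores, bw) for xi in scores])
    )
    fwd, stop_fwd = _traverse(
        scores, x0, bw, gamma0, step, tol, max_iter, angle_penalty,
        boundary_frac, boundary_ref,
    )
    stop_reason = {"forward": stop_fwd}
    if two_sided:
        bwd, stop_bwd = _traverse(
            scores, x0, bw, -gamma0, step, tol, max_iter, angle_penalty,
            boundary_frac, boundary_ref,
        )
        stop_reason["backward"] = stop_bwd
        # both traversals open with mu^{x0}; keep a single copy
        centers = bwd[:0:-1] + fwd if bwd else fwd
    else:
        centers = fwd

    # drop exactly repeated consecutive centers (stalled traversal)
    deduped = [centers[0]] if centers else []
    for c in centers[1:]:
        if np.linalg.norm(c - deduped[-1]) > 1e-12 * max(1.0, bw.mean):
            deduped.append(c)
    if len(deduped) < 2:
        raise ValueError(
            "no local structure at starting point: curve collapsed to a single center"
        )
    return LPCPath(
        centers=np.asarray(deduped),
        start_point=x0,
        # nominal step: the largest per-dimension bandwidth bounds every
        # adaptive directional step from above
        step_size=step if step is not None else bw.max,
        stop_reason=stop_reason,
        directions=2 if two_sided else 1,
    )


def choose_start(
    scores: np.ndarray,
    reference_rows: Optional[Sequence[int]] = None,
    bw: Optional[Bandwidth] = None,
    tol: Optional[float] = None,
    max_iter: int = 500,
) -> np.ndarray:
    """Starting point x0 for the traversal.

    With reference rows: their coordinate-wise mean.  Without: mean-shift
    iteration (same kernel and bandwidth) from the sample point of maximal
    kernel density, returning the converged mode.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] == 0:
        raise ValueError("empty score matrix")
    if reference_rows is not None and len(reference_rows) > 0:
        return scores[np.asarray(reference_rows, dtype=int)].mean(axis=0)
    if bw is None:
        bw = default_bandwidth(scores)
    tol = 1e-4 * bw.mean if tol is None else float(tol)
    density = [kernel_mass(xi, scores, bw) for xi in scores]
    x = scores[int(np.argmax(density))].copy()
    for _ in range(max_iter):
        x_new = local_center_of_mass(x, scores, bw)
        if np.linalg.norm(x_new - x) < tol:
            return x_new
        x = x_new
    logger.warning("mean shift did not converge in %d iterations", max_iter)
    return x
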
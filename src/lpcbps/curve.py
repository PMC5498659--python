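"""Spline interpolation of LPC centers, arc-length reparameterization, and
nearest-point projection.

The ordered centers are first given a chord-length parameterization s (sum of
Euclidean distances between consecutive centers), each coordinate is
interpolated by a natural cubic spline over s, and the projection index t is
the arc length t(s) = integral_0^s sqrt(sum_j mu_j'(u)^2) du, evaluated by
Gauss-Legendre quadrature on a dense grid.  Beyond the first and last center
the curve continues along the endpoint tangent rays, so samples lying past
the fitted span still receive distinct, monotone projection indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline, make_interp_spline
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

# 5-point Gauss-Legendre nodes/weights on [-1, 1]
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(5)


@dataclass
class Projection:
    """Nearest-point projection of one sample onto the curve."""

    sample_id: Optional[str]
    t: float  # signed arc-length index relative to the curve origin
    distance: float


@dataclass
class ParameterizedCurve:
    """Arc-length parameterized interpolant of the LPC centers.

    ``s_grid``/``t_grid`` tabulate the chord parameter against arc length on a
    dense grid (including the tangent extensions); ``origin_t`` is the raw
    arc-length value reported as t = 0.
    """

    knots_s: np.ndarray  # (L,) cumulative chord lengths, knots_s[0] == 0
    knots: np.ndarray  # (L, p) interpolated centers
    s_grid: np.ndarray
    t_grid: np.ndarray
    origin_t: float = 0.0
    _spline: object = field(default=None, repr=False)
    _grid_points: np.ndarray = field(default=None, repr=False)
    _end_tangents: tuple = field(default=None, repr=False)

    @property
    def total_length(self) -> float:
        """Arc length between the first and last center (extensions excluded)."""
        core_len = float(self.knots_s[-1])
        return float(np.interp(core_len, self.s_grid, self.t_grid))

    @property
    def t_domain(self) -> tuple:
        return (
            float(self.t_grid[0] - self.origin_t),
            float(self.t_grid[-1] - self.origin_t),
        )

    def point(self, s) -> np.ndarray:
        """Curve point(s) g(s); tangent-ray extrapolation outside the knots."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        S = float(self.knots_s[-1])
        (p0, d0), (p1, d1) = self._end_tangents
        out = np.empty((len(s), self.knots.shape[1]))
        core = (s >= 0.0) & (s <= S)
        if core.any():
            out[core] = np.atleast_2d(self._spline(s[core]))
        lo = s < 0.0
        if lo.any():
            out[lo] = p0 + s[lo, None] * d0
        hi = s > S
        if hi.any():
            out[hi] = p1 + (s[hi] - S)[:, None] * d1
        return out

    def t_of_s(self, s) -> np.ndarray:
        return np.interp(s, self.s_grid, self.t_grid)


def cumulative_chord(centers: np.ndarray) -> tuple:
    """Cumulative Euclidean chord lengths of an ordered center sequence.

    Exactly duplicated consecutive centers are dropped with a warning before
    accumulation.  Returns (s, centers) with s[0] = 0, strictly increasing.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    kept = [centers[0]]
    dropped = 0
    for c in centers[1:]:
        if np.linalg.norm(c - kept[-1]) > 0.0:
            kept.append(c)
        else:
            dropped += 1
    if dropped:
        logger.warning("dropped %d duplicate consecutive centers", dropped)
    if len(kept) < 2:
        raise ValueError("need at least 2 distinct consecutive centers")
    kept = np.asarray(kept)
    seg = np.linalg.norm(np.diff(kept, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return s, kept


def build_curve(
    centers: np.ndarray,
    grid_per_interval: int = 50,
    extension_fraction: float = 0.25,
) -> ParameterizedCurve:
    """Interpolate centers with natural cubic splines and tabulate arc length.

    With fewer than 4 centers the interpolant falls back to the matching
    lower-order spline (linear/quadratic).  Arc length is accumulated by
    5-point Gauss-Legendre quadrature of the Euclidean speed on
    ``grid_per_interval`` subdivisions per knot interval.
    """
    s_knots, pts = cumulative_chord(centers)
    L = len(s_knots)
    if L >= 4:
        spline = CubicSpline(s_knots, pts, bc_type="natural")
    else:
        spline = make_interp_spline(s_knots, pts, k=L - 1)
    deriv = spline.derivative()

    # dense s-grid over the knot span
    cells = []
    for a, b in zip(s_knots[:-1], s_knots[1:]):
        cells.append(np.linspace(a, b, grid_per_interval + 1)[:-1])
    s_core = np.concatenate(cells + [s_knots[-1:]])

    # arc length by per-cell Gauss-Legendre quadrature of the speed
    a = s_core[:-1]
    b = s_core[1:]
    half = 0.5 * (b - a)
    mid = 0.5 * (a + b)
    nodes = mid[:, None] + half[:, None] * _GL_NODES[None, :]  # (cells, 5)
    speeds = np.linalg.norm(deriv(nodes.ravel()), axis=-1).reshape(nodes.shape)
    seg_len = half * (speeds * _GL_WEIGHTS[None, :]).sum(axis=1)
    if np.any(seg_len <= 0):
        raise ValueError("arc length not strictly increasing (degenerate spline)")
    t_core = np.concatenate([[0.0], np.cumsum(seg_len)])

    # tangent-ray extensions beyond both ends
    S = float(s_knots[-1])
    d0 = np.atleast_1d(deriv(0.0)).astype(float)
    d1 = np.atleast_1d(deriv(S)).astype(float)
    p0 = np.atleast_1d(spline(0.0)).astype(float)
    p1 = np.atleast_1d(spline(S)).astype(float)
    sp0 = float(np.linalg.norm(d0))
    sp1 = float(np.linalg.norm(d1))
    ext = extension_fraction * S
    if ext > 0 and sp0 > 0 and sp1 > 0:
        n_ext = max(grid_per_interval, 2)
        s_lo = np.linspace(-ext, 0.0, n_ext + 1)[:-1]
        s_hi = np.linspace(S, S + ext, n_ext + 1)[1:]
        s_grid = np.concatenate([s_lo, s_core, s_hi])
        t_grid = np.concatenate(
            [s_lo * sp0, t_core, t_core[-1] + (s_hi - S) * sp1]
        )
    else:
        s_grid = s_core
        t_grid = t_core

    curve = ParameterizedCurve(
        knots_s=s_knots,
        knots=pts,
        s_grid=s_grid,
        t_grid=t_grid,
        origin_t=0.0,
        _spline=spline,
        _end_tangents=((p0, d0), (p1, d1)),
    )
    curve._grid_points = curve.point(s_grid)
    return curve


def _project_raw(
    curve: ParameterizedCurve, x: np.ndarray, refine: bool = True
) -> tuple:
    """(s*, t_raw, distance) of the nearest curve point; ties toward smaller t."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    d2 = ((curve._grid_points - x) ** 2).sum(axis=1)
    i = int(np.argmin(d2))  # first minimum -> smaller s -> smaller t
    s_best = float(curve.s_grid[i])
    d2_best = float(d2[i])
    if refine:
        a = float(curve.s_grid[max(i - 1, 0)])
        b = float(curve.s_grid[min(i + 1, len(curve.s_grid) - 1)])
        if b > a:
            res = minimize_scalar(
                lambda s: float(((curve.point(s)[0] - x) ** 2).sum()),
                bounds=(a, b),
                method="bounded",
                options={"xatol": 1e-12 * max(1.0, b - a)},
            )
            if res.fun < d2_best:
                s_best, d2_best = float(res.x), float(res.fun)
    t_raw = float(np.interp(s_best, curve.s_grid, curve.t_grid))
    return s_best, t_raw, float(np.sqrt(d2_best))


def project_point(
    curve: ParameterizedCurve,
    x: np.ndarray,
    sample_id: Optional[str] = None,
    refine: bool = True,
) -> Projection:
    """Project one point onto the curve: nearest Euclidean distance, index
    reported relative to the curve origin."""
    _, t_raw, dist = _project_raw(curve, x, refine=refine)
    return Projection(sample_id=sample_id, t=t_raw - curve.origin_t, distance=dist)


def project_points(
    curve: ParameterizedCurve, X: np.ndarray, refine: bool = True
) -> tuple:
    """Vectorized projection of rows of X; returns (t, distance) arrays."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    t = np.empty(len(X))
    d = np.empty(len(X))
    for i, x in enumerate(X):
        _, t_raw, dist = _project_raw(curve, x, refine=refine)
        t[i] = t_raw - curve.origin_t
        d[i] = dist
    return t, d


def set_origin(curve: ParameterizedCurve, f0: np.ndarray) -> ParameterizedCurve:
    """Anchor t = 0 at the projection of ``f0`` (e.g. the normal-sample start).

    Subsequent projections report t minus this origin; when f0 projects to the
    curve's start the behavior reduces to raw arc length.
    """
    _, t_raw, _ = _project_raw(curve, f0, refine=True)
    return replace(curve, origin_t=t_raw)
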
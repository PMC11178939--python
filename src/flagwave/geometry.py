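"""Differential geometry of traced curves.

Tangent angles are measured against the +x image axis at anchors spaced
every ``step_px`` of *arc length* (not point index — manual clicks are
unevenly spaced), with the tangent direction taken as the total-least-squares
line through all points within a ``window_px``-long arc window centred on
the anchor. Curvature uses an algebraic (Kåsa) circle fit over the same
windows, |kappa| = 1/r, signed by the local turning direction: positive
where the tangent angle increases along the arc.

All operations are rotation/translation equivariant; none reorders points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .trace_io import UNIT_MICRON, Trace

#: Lateral RMS deviation below this fraction of the window arc length means
#: the window is collinear: the circle degenerates to a line, kappa = 0.
DEGENERACY_TOL = 1e-6


@dataclass
class TangentProfile:
    """Unwrapped tangent angles theta(s) for one frame (s in um, theta in rad)."""

    s: np.ndarray
    theta: np.ndarray
    frame_index: int
    time_s: float

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.s.shape != self.theta.shape:
            raise InputError("s and theta must have equal length")
        if self.s.ndim != 1 or self.s.size < 2:
            raise InputError("profile needs >= 2 samples")
        if np.any(np.diff(self.s) <= 0):
            raise InputError("s must be strictly increasing")


@dataclass
class CircleFit:
    center: tuple[float, float]
    r: float
    rms_residual: float
    degenerate: bool

    @property
    def curvature(self) -> float:
        return 0.0 if self.degenerate else 1.0 / self.r


@dataclass
class CurvatureProfile:
    """Signed curvature kappa(s) for one frame, on the tangent-profile grid."""

    s: np.ndarray
    kappa: np.ndarray
    frame_index: int
    time_s: float

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.kappa = np.asarray(self.kappa, dtype=float)
        if self.s.shape != self.kappa.shape:
            raise InputError("s and kappa must have equal length")


def _points_of(trace) -> np.ndarray:
    if isinstance(trace, Trace):
        return trace.points
    pts = np.asarray(trace, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InputError("expected an (n, 2) coordinate array or a Trace")
    return pts


def cumulative_arclength(trace) -> np.ndarray:
    """Cumulative length from the head: s[0] = 0, s[i] = s[i-1] + |p_i - p_{i-1}|."""
    pts = _points_of(trace)
    if pts.shape[0] < 2:
        raise InputError("need >= 2 points for an arc length")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg == 0.0):
        raise InputError("duplicate consecutive points (zero-length segment)")
    return np.concatenate([[0.0], np.cumsum(seg)])


def wrap_angle(theta):
    """Wrap angle(s) into the half-open interval (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(theta, dtype=float), 2.0 * np.pi)


def unwrap_angles(theta_raw) -> np.ndarray:
    """Unwrap a sequence of angles.

    The output equals the input modulo 2*pi element-wise, adjacent
    differences lie in (-pi, pi], and the first element lies in (-pi, pi].
    """
    th = np.asarray(theta_raw, dtype=float).ravel()
    if th.size == 0:
        raise InputError("empty angle sequence")
    out = np.empty_like(th)
    out[0] = wrap_angle(th[0])
    if th.size > 1:
        out[1:] = out[0] + np.cumsum(wrap_angle(np.diff(th)))
    return out


def fit_circle(points) -> CircleFit:
    """Algebraic least-squares (Kasa) circle through >= 3 points.

    Minimizes sum((|p - c|^2 - r^2)^2), which is linear in (2cx, 2cy,
    r^2 - |c|^2). Collinear windows (lateral RMS below DEGENERACY_TOL of the
    window arc length) are reported degenerate with r = +inf.
    """
    pts = _points_of(points)
    if pts.shape[0] < 3:
        raise InputError("circle fit needs >= 3 points")
    x, y = pts[:, 0], pts[:, 1]
    mx, my = x.mean(), y.mean()
    cxx = np.mean(x * x) - mx * mx
    cyy = np.mean(y * y) - my * my
    cxy = np.mean(x * y) - mx * my
    half_tr = 0.5 * (cxx + cyy)
    disc = np.sqrt(max(0.25 * (cxx - cyy) ** 2 + cxy * cxy, 0.0))
    lateral_rms = np.sqrt(max(half_tr - disc, 0.0))
    arclen = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    if lateral_rms < DEGENERACY_TOL * arclen:
        return CircleFit(
            center=(np.nan, np.nan),
            r=np.inf,
            rms_residual=float(lateral_rms),
            degenerate=True,
        )
    # solve in centered coordinates for conditioning
    u, v = x - mx, y - my
    a = np.column_stack([u, v, np.ones_like(u)])
    b = u * u + v * v
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    cx, cy = mx + 0.5 * sol[0], my + 0.5 * sol[1]
    r2 = sol[2] + 0.25 * (sol[0] ** 2 + sol[1] ** 2)
    r = float(np.sqrt(max(r2, 0.0)))
    dist = np.hypot(x - cx, y - cy)
    rms = float(np.sqrt(np.mean((dist - r) ** 2)))
    return CircleFit(center=(float(cx), float(cy)), r=r, rms_residual=rms, degenerate=False)


def fit_circle_geometric(points, initial: CircleFit | None = None) -> CircleFit:
    """Geometric least-squares circle: direct minimization of sum((|p-c|-r)^2).

    Slower than the Kasa fit; retained as an independent reference
    implementation (and cross-check oracle) rather than a pipeline stage.
    """
    from scipy.optimize import least_squares

    pts = _points_of(points)
    if pts.shape[0] < 3:
        raise InputError("circle fit needs >= 3 points")
    init = initial if initial is not None else fit_circle(pts)
    if init.degenerate:
        return init
    x0 = np.array([init.center[0], init.center[1], init.r])

    def resid(p):
        return np.hypot(pts[:, 0] - p[0], pts[:, 1] - p[1]) - p[2]

    sol = least_squares(resid, x0, method="lm")
    cx, cy, r = sol.x
    rms = float(np.sqrt(np.mean(resid(sol.x) ** 2)))
    return CircleFit(center=(float(cx), float(cy)), r=float(abs(r)), rms_residual=rms, degenerate=False)


# ---------------------------------------------------------------------------
# windowed profiles
# ---------------------------------------------------------------------------


def _require_micron_trace(trace) -> np.ndarray:
    if isinstance(trace, Trace) and trace.unit != UNIT_MICRON:
        raise InputError("trace must be in micron units (run to_microns first)")
    return _points_of(trace)


def _prefix(a: np.ndarray) -> np.ndarray:
    out = np.empty(a.size + 1)
    out[0] = 0.0
    np.cumsum(a, out=out[1:])
    return out


def profile_pair(
    trace,
    *,
    step_px: int = 10,
    window_px: int = 20,
    pixel_size_um: float,
) -> tuple[TangentProfile, CurvatureProfile]:
    """Tangent-angle and signed-curvature profiles on one shared arc grid.

    Anchors start at arc length = half the window and advance every
    ``step_px * pixel_size_um`` of arc length; only anchors whose full
    window fits within the trace are emitted. Windows holding fewer than 3
    points are dropped (the two profiles always stay sample-aligned).

    Raises InputError("trace too short") when fewer than 2 samples survive.
    """
    pts = _require_micron_trace(trace)
    if pixel_size_um <= 0:
        raise InputError("pixel_size_um must be > 0")
    step_um = step_px * pixel_size_um
    window_um = window_px * pixel_size_um
    hw = 0.5 * window_um
    s = cumulative_arclength(pts)
    total = s[-1]
    if total < window_um + step_um:
        raise InputError("trace too short for the requested window/step")
    anchors = np.arange(hw, total - hw + 1e-12, step_um)
    i0 = np.searchsorted(s, anchors - hw, side="left")
    i1 = np.searchsorted(s, anchors + hw, side="right")
    n = (i1 - i0).astype(float)
    valid = (i1 - i0) >= 3
    if np.count_nonzero(valid) < 2:
        raise InputError("trace too short (fewer than 2 usable windows)")

    # Gather every window into a padded (n_windows, max_len) block and work
    # in *window-local* coordinates (origin at each window's mean). Moments
    # of global coordinates cancel catastrophically for shallow arcs far
    # from the origin — the circle center is conditioned like (r/w)^2 — so
    # locality here is what buys the 1e-10-level rotation invariance.
    max_len = int(np.max(i1 - i0))
    col = np.arange(max_len)
    idx = np.minimum(i0[:, None] + col[None, :], len(pts) - 1)
    mask = col[None, :] < (i1 - i0)[:, None]
    wx = np.where(mask, pts[idx, 0], 0.0)
    wy = np.where(mask, pts[idx, 1], 0.0)
    mx = wx.sum(axis=1) / n
    my = wy.sum(axis=1) / n
    u = np.where(mask, wx - mx[:, None], 0.0)
    v = np.where(mask, wy - my[:, None], 0.0)
    su2 = np.sum(u * u, axis=1)
    sv2 = np.sum(v * v, axis=1)
    suv = np.sum(u * v, axis=1)
    cxx, cyy, cxy = su2 / n, sv2 / n, suv / n
    su3 = np.sum(u**3, axis=1)
    sv3 = np.sum(v**3, axis=1)
    su2v = np.sum(u * u * v, axis=1)
    suv2 = np.sum(u * v * v, axis=1)

    # --- tangent: principal axis of the window's covariance ---
    ang = 0.5 * np.arctan2(2.0 * cxy, cxx - cyy)
    chord = pts[np.clip(i1 - 1, 0, len(pts) - 1)] - pts[i0]
    flip = np.cos(ang) * chord[:, 0] + np.sin(ang) * chord[:, 1] < 0.0
    ang = np.where(flip, ang + np.pi, ang)

    # --- degeneracy: lateral RMS about the principal axis ---
    disc = np.sqrt(np.maximum(0.25 * (cxx - cyy) ** 2 + cxy * cxy, 0.0))
    lateral_rms = np.sqrt(np.maximum(0.5 * (cxx + cyy) - disc, 0.0))
    wlen = s[np.clip(i1 - 1, 0, len(pts) - 1)] - s[i0]
    degenerate = lateral_rms < DEGENERACY_TOL * np.maximum(wlen, 1e-300)

    # --- Kasa circle fit per window, in window-centered coordinates the
    # normal equations decouple to a 2x2 system:
    #   [su2 suv; suv sv2] (a, b)^T = (su3 + suv2, su2v + sv3)^T
    # with circle center (a/2, b/2) relative to the window mean and
    # r^2 = (su2 + sv2)/n + (a/2)^2 + (b/2)^2.
    rhs_u = su3 + suv2
    rhs_v = su2v + sv3
    det = su2 * sv2 - suv * suv
    solvable = valid & ~degenerate & (det > 0.0)
    safe_det = np.where(solvable, det, 1.0)
    a_sol = (sv2 * rhs_u - suv * rhs_v) / safe_det
    b_sol = (su2 * rhs_v - suv * rhs_u) / safe_det
    r2 = (su2 + sv2) / n + 0.25 * (a_sol**2 + b_sol**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa_mag = np.where(solvable, 1.0 / np.sqrt(np.maximum(r2, 1e-300)), 0.0)
    degenerate = degenerate | (valid & (det <= 0.0))

    # --- sign: net turning direction (cross products of successive chords) ---
    u = np.diff(pts, axis=0)
    cross = u[:-1, 0] * u[1:, 1] - u[:-1, 1] * u[1:, 0]
    pc = _prefix(cross)
    lo = np.clip(i0, 0, cross.size)
    hi = np.clip(i1 - 2, 0, cross.size)
    hi = np.maximum(hi, lo)
    net_turn = pc[hi] - pc[lo]
    sign = np.where(net_turn < 0.0, -1.0, 1.0)

    kappa = np.where(degenerate, 0.0, sign * kappa_mag)

    frame_index = trace.frame_index if isinstance(trace, Trace) else 0
    time_s = trace.time_s if isinstance(trace, Trace) else 0.0
    sv = anchors[valid]
    theta = unwrap_angles(ang[valid])
    tp = TangentProfile(s=sv, theta=theta, frame_index=frame_index, time_s=time_s)
    cp = CurvatureProfile(s=sv, kappa=kappa[valid], frame_index=frame_index, time_s=time_s)
    return tp, cp


def tangent_profile(
    trace, *, step_px: int = 10, window_px: int = 20, pixel_size_um: float
) -> TangentProfile:
    """Windowed tangent angles theta(s); see profile_pair for conventions."""
    tp, _ = profile_pair(
        trace, step_px=step_px, window_px=window_px, pixel_size_um=pixel_size_um
    )
    return tp


def curvature_profile(
    trace, *, window_px: int = 20, step_px: int = 10, pixel_size_um: float
) -> CurvatureProfile:
    """Signed curvature kappa(s) = +/- 1/r from sliding circle fits."""
    _, cp = profile_pair(
        trace, step_px=step_px, window_px=window_px, pixel_size_um=pixel_size_um
    )
    return cp
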
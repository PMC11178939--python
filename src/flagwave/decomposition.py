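"""Static/dynamic decomposition of tangent-angle profiles.

The central statistic is the *basal curvature*: tangent angles from at least
``min_frames_per_cycle`` time points spanning one beat cycle are pooled and
fitted with a single straight line theta = slope * s + intercept by ordinary
least squares; the slope (rad/um) is the basal curvature, the static
component of the waveform. Subtracting the fitted line from each frame's
profile leaves the dynamic (propagating) component.

The *asymmetry index* compares the two bend extremes of the signed
curvature at a fixed arc position (10 um from the head by default) over one
cycle: index = |kappa_max| / |kappa_min| >= 1, the stronger bend being the
P-bend, the weaker the R-bend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .errors import AnalysisError, InputError
from .geometry import CurvatureProfile, TangentProfile, profile_pair
from .kinematics import (
    BeatEstimate,
    estimate_beat_frequency,
    probe_signal,
    select_cycle_frames,
)
from .trace_io import UNIT_MICRON, FlagellumResult, TraceSet, to_microns


@dataclass
class StaticFit:
    """Pooled linear fit of theta on s; slope = basal curvature (rad/um)."""

    slope: float
    intercept: float
    n_points: int
    r_squared: float
    shifted: bool = False

    def predict(self, s) -> np.ndarray:
        return self.slope * np.asarray(s, dtype=float) + self.intercept


@dataclass
class DynamicComponent:
    """Per-frame residual profiles theta'(s, t) = theta(s, t) - fit line."""

    residuals: list[TangentProfile]
    fit: StaticFit

    def reconstruct(self) -> list[TangentProfile]:
        """Add the static line back; recovers the inputs exactly."""
        return [
            TangentProfile(
                s=p.s,
                theta=p.theta + self.fit.predict(p.s),
                frame_index=p.frame_index,
                time_s=p.time_s,
            )
            for p in self.residuals
        ]


@dataclass
class CurvatureSeries:
    """Signed curvature at one arc position across frames."""

    position_um: float
    frame_indices: list[int]
    times: np.ndarray
    kappa: np.ndarray
    qc_flags: list[str] = field(default_factory=list)


@dataclass
class AsymmetryResult:
    kappa_max: float
    kappa_min: float
    index: float | None
    p_bend_frame: int | None
    r_bend_frame: int | None
    position_um: float
    qc_flags: list[str] = field(default_factory=list)


def fit_static_component(
    profiles: list[TangentProfile], shift_to_origin: bool = False
) -> StaticFit:
    """OLS of theta on s over the pooled samples of all profiles.

    Single-profile input is allowed (single-frame quantification of immotile
    flagella). ``shift_to_origin`` marks the fit for presentation with the
    intercept removed (see shift_profiles); it never changes the slope.
    """
    if not profiles:
        raise InputError("need >= 1 profile")
    s = np.concatenate([p.s for p in profiles])
    theta = np.concatenate([p.theta for p in profiles])
    if s.size < 2:
        raise InputError("need >= 2 pooled points")
    if np.ptp(s) == 0.0:
        raise InputError("degenerate abscissa: all s identical")
    slope, intercept = np.polyfit(s, theta, 1)
    resid = theta - (slope * s + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((theta - theta.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return StaticFit(
        slope=float(slope),
        intercept=float(intercept),
        n_points=int(s.size),
        r_squared=float(r_squared),
        shifted=bool(shift_to_origin),
    )


def shift_profiles(
    profiles: list[TangentProfile], fit: StaticFit
) -> tuple[list[TangentProfile], StaticFit]:
    """Translate the plot so the fitted line passes through the origin.

    Presentation-only: every theta is lowered by the intercept, so the line
    becomes theta = slope * s. The slope is untouched.
    """
    shifted = [
        TangentProfile(
            s=p.s,
            theta=p.theta - fit.intercept,
            frame_index=p.frame_index,
            time_s=p.time_s,
        )
        for p in profiles
    ]
    return shifted, StaticFit(
        slope=fit.slope,
        intercept=0.0,
        n_points=fit.n_points,
        r_squared=fit.r_squared,
        shifted=True,
    )


def dynamic_component(
    profiles: list[TangentProfile], fit: StaticFit
) -> DynamicComponent:
    """Subtract the static line from each tangent-angle profile."""
    if not profiles:
        raise InputError("need >= 1 profile")
    residuals = []
    for p in profiles:
        if p.s.shape != p.theta.shape:
            raise InputError("grid mismatch between s and theta")
        residuals.append(
            TangentProfile(
                s=p.s,
                theta=p.theta - fit.predict(p.s),
                frame_index=p.frame_index,
                time_s=p.time_s,
            )
        )
    return DynamicComponent(residuals=residuals, fit=fit)


def curvature_at_position(
    profiles: list[CurvatureProfile], position_um: float
) -> CurvatureSeries:
    """Interpolate each frame's signed curvature at one arc position.

    Frames whose traced length does not reach the position are excluded
    with a QC flag rather than zero-filled.
    """
    if not profiles:
        raise InputError("need >= 1 curvature profile")
    frames, times, kappa, qc = [], [], [], []
    for p in profiles:
        if position_um < p.s[0] or position_um > p.s[-1]:
            qc.append(f"frame{p.frame_index}:curvature_position_outside_trace")
            continue
        frames.append(p.frame_index)
        times.append(p.time_s)
        kappa.append(float(np.interp(position_um, p.s, p.kappa)))
    if not frames:
        raise InputError(f"no frame covers arc position {position_um} um")
    return CurvatureSeries(
        position_um=float(position_um),
        frame_indices=frames,
        times=np.asarray(times),
        kappa=np.asarray(kappa),
        qc_flags=qc,
    )


def asymmetry_index(
    series: CurvatureSeries,
    *,
    curvature_floor: float = 1e-4,
    mode: str = "magnitude",
    min_frames: int = 2,
) -> AsymmetryResult:
    """Ratio of the two bend-curvature extremes over one beat cycle.

    ``magnitude`` (default): index = |stronger extreme| / |weaker extreme|,
    which is 1 for a symmetric beat and grows with static bias; the frame of
    the stronger extreme is labeled P-bend, the weaker R-bend. ``signed``
    divides the raw signed extremes instead (max / min). When the weaker
    extreme's magnitude falls below ``curvature_floor`` the index is
    undefined (near-straight recovery bend) and flagged.
    """
    if mode not in ("magnitude", "signed"):
        raise InputError(f"unknown asymmetry mode {mode!r}")
    if series.kappa.size < min_frames:
        raise InputError("too few frames for an asymmetry index")
    qc = list(series.qc_flags)
    i_max = int(np.argmax(series.kappa))
    i_min = int(np.argmin(series.kappa))
    k_hi, k_lo = float(series.kappa[i_max]), float(series.kappa[i_min])
    if abs(k_lo) > abs(k_hi):
        i_p, i_r = i_min, i_max
        mag_hi, mag_lo = abs(k_lo), abs(k_hi)
    else:
        i_p, i_r = i_max, i_min
        mag_hi, mag_lo = abs(k_hi), abs(k_lo)
    if mag_lo < curvature_floor:
        qc.append("near-straight recovery bend")
        return AsymmetryResult(
            kappa_max=k_hi,
            kappa_min=k_lo,
            index=None,
            p_bend_frame=series.frame_indices[i_p],
            r_bend_frame=series.frame_indices[i_r],
            position_um=series.position_um,
            qc_flags=qc,
        )
    index = mag_hi / mag_lo if mode == "magnitude" else k_hi / k_lo
    return AsymmetryResult(
        kappa_max=k_hi,
        kappa_min=k_lo,
        index=float(index),
        p_bend_frame=series.frame_indices[i_p],
        r_bend_frame=series.frame_indices[i_r],
        position_um=series.position_um,
        qc_flags=qc,
    )


# ---------------------------------------------------------------------------
# end-to-end per-flagellum analysis
# ---------------------------------------------------------------------------


def analyze_flagellum(
    trace_set: TraceSet, config: RunConfig | None = None
) -> FlagellumResult:
    """Full per-flagellum pipeline: profiles → beat estimate → decomposition.

    Motile flagella: frames spanning one beat cycle are selected and pooled
    into the static fit; the asymmetry index is read at the configured arc
    position. Immotile flagella: a single frame is drawn with the seeded RNG
    (seed recorded in qc_flags) and fitted alone; frequency and index stay
    undefined. Deterministic given the trace set and config.
    """
    cfg = config if config is not None else RunConfig()
    ts = trace_set if trace_set.unit == UNIT_MICRON else to_microns(trace_set)
    qc: list[str] = list(ts.qc_flags)

    tangent, curvature = [], []
    for tr in ts.traces:
        try:
            tp, cp = profile_pair(
                tr,
                step_px=cfg.step_px,
                window_px=cfg.window_px,
                pixel_size_um=ts.pixel_size_um,
            )
        except InputError as exc:
            qc.append(f"frame{tr.frame_index}:profile_failed:{exc}")
            continue
        tangent.append(tp)
        curvature.append(cp)
    if not tangent:
        raise AnalysisError("geometry", f"{ts.flagellum_id}: no usable frames")
    curvature_by_frame = {cp.frame_index: cp for cp in curvature}

    if len(tangent) >= 4:
        common_arc = min(p.s[-1] for p in tangent)
        s_probe = cfg.probe_fraction * common_arc
        try:
            probe = probe_signal(tangent, s_probe)
            beat = estimate_beat_frequency(
                probe.theta,
                ts.fps,
                snr_threshold=cfg.snr_threshold,
                amplitude_threshold_rad=cfg.amplitude_threshold_rad,
                method=cfg.frequency_method,
            )
            qc.extend(probe.qc_flags)
        except InputError as exc:
            qc.append(f"beat_estimate_failed:{exc}")
            beat = BeatEstimate(None, None, cfg.frequency_method, snr=0.0, motile=False)
    else:
        qc.append("too_few_frames_for_beat_estimate")
        beat = BeatEstimate(None, None, cfg.frequency_method, snr=0.0, motile=False)

    asym_value: float | None = None
    if beat.motile:
        full_cycle = True
        try:
            cycle = select_cycle_frames(
                tangent, beat, min_frames=cfg.min_frames_per_cycle
            )
        except InputError as exc:
            if len(tangent) < cfg.min_frames_per_cycle:
                raise AnalysisError(
                    "cycle_selection", f"{ts.flagellum_id}: {exc}"
                ) from exc
            # recoverable: pool every frame instead of one selected cycle,
            # but the asymmetry index stays undefined (no full cycle sampled)
            qc.append(f"cycle_selection_failed_using_all_frames:{exc}")
            cycle = tangent
            full_cycle = False
        fit = fit_static_component(cycle, shift_to_origin=cfg.shift_to_origin)
        used = [curvature_by_frame[p.frame_index] for p in cycle]
        if not full_cycle:
            qc.append("asymmetry_undefined:no_full_cycle_sampled")
        else:
            try:
                series = curvature_at_position(used, cfg.asymmetry_position_um)
                asym = asymmetry_index(
                    series,
                    curvature_floor=cfg.curvature_floor,
                    mode=cfg.asymmetry_mode,
                    min_frames=min(cfg.min_frames_per_cycle, len(series.kappa)),
                )
                qc.extend(asym.qc_flags)
                asym_value = asym.index
            except InputError as exc:
                qc.append(f"asymmetry_undefined:{exc}")
        n_used = len(cycle)
        freq = beat.frequency_hz
    else:
        rng = np.random.default_rng(cfg.immotile_frame_seed)
        pick = int(rng.integers(len(tangent)))
        frame = tangent[pick]
        qc.append(
            f"immotile:seed={cfg.immotile_frame_seed}:frame={frame.frame_index}"
        )
        fit = fit_static_component([frame], shift_to_origin=cfg.shift_to_origin)
        used = [curvature_by_frame[frame.frame_index]]
        n_used = 1
        freq = None

    mean_abs_curv = float(np.mean([np.mean(np.abs(cp.kappa)) for cp in used]))

    return FlagellumResult(
        flagellum_id=ts.flagellum_id,
        genotype=ts.genotype,
        condition=ts.condition,
        n_frames_used=n_used,
        basal_curvature=fit.slope,
        intercept=fit.intercept,
        asymmetry_index=asym_value,
        beat_frequency_hz=freq,
        qc_flags=qc,
        mean_abs_curvature=mean_abs_curv,
    )
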
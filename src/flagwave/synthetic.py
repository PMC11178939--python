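"""Generative model of planar flagellar beating with known ground truth.

The kinematic model is a traveling curvature wave on top of a static
curvature offset:

    kappa(s, t) = kappa0(s) + amp(s) * sin(2*pi*(s/wavelength - f*t) + phase0)

integrated to tangent angles and positions with the head clamped at the
origin (head fixed, flagellum free — the observation geometry of the
recordings this emulates). Traces are emitted at a configurable click
density, perturbed with Gaussian point noise, and quantized to the pixel
grid to mimic manual tracing on upscaled video frames.

``kappa0`` may be piecewise-constant in s and ``amp`` may carry an envelope
(proximal ramp, optional inactive distal region) so that every phenotype of
interest can be generated: symmetric beating, calcium-induced asymmetric
beating, biphasic proximal-active/distal-inactive beating, and statically
curved immotile flagella.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import InputError
from .trace_io import (
    UNIT_MICRON,
    UNIT_PIXEL,
    Trace,
    TraceSet,
    merge_duplicate_points,
)

#: Integration step (um) for shape integration; well below any feature scale.
FINE_DS = 0.02


@dataclass
class WaveParams:
    """Ground-truth parameters of one simulated flagellum."""

    length_um: float = 30.0
    kappa0: float = 0.0  # static curvature, 1/um (proximal value if biphasic)
    kappa0_distal: float | None = None  # distal static curvature (biphasic)
    kappa0_break_um: float | None = None  # arc position of the static break
    amp: float = 0.10  # dynamic curvature amplitude, 1/um
    amp_envelope: str = "none"  # none | ramp | biphasic
    ramp_um: float = 2.0  # proximal bend-growth ramp length
    active_length_um: float | None = None  # distal inactive beyond this (biphasic)
    wavelength_um: float = 30.0
    freq_hz: float = 2.0
    phase0: float = 0.0
    theta_head: float = 0.0
    noise_sigma_um: float = 0.05
    pixel_size_um: float = 0.04
    fps: float = 100.0
    duration_s: float = 2.0
    points_per_um: float = 25.0
    click_spacing_um: float | None = 0.4
    noise_corr_um: float | None = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("length_um", "wavelength_um", "freq_hz", "fps", "duration_s", "points_per_um"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be > 0")
        if self.amp < 0:
            raise InputError("amp must be >= 0")
        if self.noise_sigma_um < 0:
            raise InputError("noise_sigma_um must be >= 0")
        if self.amp_envelope not in ("none", "ramp", "biphasic"):
            raise InputError(f"unknown amp_envelope {self.amp_envelope!r}")
        if self.amp_envelope == "biphasic" and self.active_length_um is None:
            raise InputError("biphasic envelope needs active_length_um")

    def replace(self, **updates) -> "WaveParams":
        return dataclasses.replace(self, **updates)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _kappa0_of(params: WaveParams, s: np.ndarray) -> np.ndarray:
    if params.kappa0_distal is None or params.kappa0_break_um is None:
        return np.full_like(s, params.kappa0)
    return np.where(s < params.kappa0_break_um, params.kappa0, params.kappa0_distal)


def _amp_of(params: WaveParams, s: np.ndarray) -> np.ndarray:
    amp = np.full_like(s, params.amp)
    if params.amp_envelope in ("ramp", "biphasic"):
        amp = amp * np.minimum(s / params.ramp_um, 1.0)
    if params.amp_envelope == "biphasic":
        amp = np.where(s <= params.active_length_um, amp, 0.0)
    return amp


def curvature_field(params: WaveParams, s, t) -> np.ndarray:
    """kappa(s, t) of the traveling-wave model; broadcasts over s and t."""
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    phase = (
        2.0 * np.pi * (s / params.wavelength_um - params.freq_hz * t)
        + params.phase0
    )
    return _kappa0_of(params, s) + _amp_of(params, s) * np.sin(phase)


def _fine_grid(params: WaveParams) -> np.ndarray:
    n = int(np.ceil(params.length_um / FINE_DS))
    return np.linspace(0.0, params.length_um, n + 1)


def _grid_to(length: float, spacing: float) -> np.ndarray:
    s = np.arange(0.0, length + 0.5 * spacing, spacing)
    if s[-1] < length:
        s = np.append(s, length)
    return np.minimum(s, length)


def _emit_grid(params: WaveParams) -> np.ndarray:
    return _grid_to(params.length_um, 1.0 / params.points_per_um)


def _tracing_noise(
    params: WaveParams, rng: np.random.Generator, click_grid: np.ndarray, n_frames: int
) -> np.ndarray:
    """Per-click tracing error, (n_frames, n_clicks, 2).

    A human retracing a filament makes errors that are smooth *along* the
    filament (the cursor drifts off-axis over microns, it does not jitter
    click to click), so the error field is Gaussian at control knots every
    ``noise_corr_um`` of arc, linearly interpolated to the clicks, with
    fresh draws per frame. ``noise_corr_um = None`` falls back to iid noise
    per click.
    """
    sigma = params.noise_sigma_um
    if params.noise_corr_um is None:
        return rng.normal(0.0, sigma, (n_frames, click_grid.size, 2))
    knot_grid = _grid_to(params.length_um, params.noise_corr_um)
    knots = rng.normal(0.0, sigma, (n_frames, knot_grid.size, 2))
    if knot_grid.size < 2:
        return np.repeat(knots, click_grid.size, axis=1)
    idx = np.clip(np.searchsorted(knot_grid, click_grid), 1, knot_grid.size - 1)
    w = (click_grid - knot_grid[idx - 1]) / (knot_grid[idx] - knot_grid[idx - 1])
    return (
        knots[:, idx - 1, :] * (1.0 - w)[None, :, None]
        + knots[:, idx, :] * w[None, :, None]
    )


def _integrate_frames(params: WaveParams, times: np.ndarray):
    """Vectorized shape integration for many frames at once.

    Returns (s_fine, x, y) with x, y of shape (n_frames, n_fine). The curve
    is parameterized by arc length, so interpolation against s_fine is an
    exact resampling of the unit-speed curve.
    """
    s = _fine_grid(params)
    kappa = curvature_field(params, s[None, :], times[:, None])
    theta = params.theta_head + cumulative_trapezoid(kappa, s, axis=1, initial=0.0)
    x = cumulative_trapezoid(np.cos(theta), s, axis=1, initial=0.0)
    y = cumulative_trapezoid(np.sin(theta), s, axis=1, initial=0.0)
    return s, x, y


def integrate_shape(params: WaveParams, t: float, frame_index: int = 0) -> Trace:
    """Noiseless flagellum shape at time t, head clamped at the origin."""
    s, x, y = _integrate_frames(params, np.array([float(t)]))
    se = _emit_grid(params)
    pts = np.column_stack([np.interp(se, s, x[0]), np.interp(se, s, y[0])])
    return Trace(frame_index=frame_index, time_s=float(t), points=pts, unit=UNIT_MICRON)


def render_trace_set(
    params: WaveParams,
    *,
    flagellum_id: str = "sim",
    condition: str = "",
    genotype: str = "",
    quantize: bool = True,
) -> tuple[TraceSet, dict]:
    """Render a full recording: frames at fps over duration_s.

    Per point, isotropic Gaussian noise (sigma = noise_sigma_um) is added
    and, when ``quantize`` is set, positions are snapped to the pixel grid
    and returned in pixel units (micron units otherwise). Deterministic
    given ``params.seed``. Returns the TraceSet and a ground-truth record
    holding the full parameter set.
    """
    rng = np.random.default_rng(params.seed)
    n_frames = int(round(params.fps * params.duration_s))
    if n_frames < 1:
        raise InputError("duration_s * fps must yield at least one frame")
    times = np.arange(n_frames) / params.fps

    s, x, y = _integrate_frames(params, times)

    def _resample(grid: np.ndarray) -> np.ndarray:
        idx = np.clip(np.searchsorted(s, grid), 1, s.size - 1)
        w = (grid - s[idx - 1]) / (s[idx] - s[idx - 1])
        xe = x[:, idx - 1] * (1.0 - w) + x[:, idx] * w
        ye = y[:, idx - 1] * (1.0 - w) + y[:, idx] * w
        return np.stack([xe, ye], axis=-1)  # (frames, points, 2)

    if params.click_spacing_um is not None and (params.noise_sigma_um > 0 or quantize):
        # Manual-tracing model: noisy, pixel-snapped clicks every
        # click_spacing_um, then dense exact interpolation along the click
        # polyline — the coordinate list ImageJ exports for a segmented line.
        click_grid = _grid_to(params.length_um, params.click_spacing_um)
        clicks = _resample(click_grid)
        if params.noise_sigma_um > 0:
            clicks = clicks + _tracing_noise(params, rng, click_grid, n_frames)
        if quantize:
            clicks = np.rint(clicks / params.pixel_size_um) * params.pixel_size_um
        emitted = []
        for k in range(n_frames):
            seg = np.linalg.norm(np.diff(clicks[k], axis=0), axis=1)
            arc = np.concatenate([[0.0], np.cumsum(seg)])
            grid = _grid_to(arc[-1], 1.0 / params.points_per_um)
            emitted.append(
                np.column_stack(
                    [
                        np.interp(grid, arc, clicks[k, :, 0]),
                        np.interp(grid, arc, clicks[k, :, 1]),
                    ]
                )
            )
        coords = emitted
    else:
        # Literal per-point model: noise and quantization on every emitted
        # point. Only sensible when noise_sigma_um is small relative to the
        # emitted point spacing.
        dense = _resample(_emit_grid(params))
        if params.noise_sigma_um > 0:
            dense = dense + rng.normal(0.0, params.noise_sigma_um, dense.shape)
        if quantize:
            dense = np.rint(dense / params.pixel_size_um) * params.pixel_size_um
        coords = [dense[k] for k in range(n_frames)]

    if quantize:
        coords = [c / params.pixel_size_um for c in coords]
        unit = UNIT_PIXEL
    else:
        unit = UNIT_MICRON

    traces: list[Trace] = []
    qc: list[str] = []
    merged_total = 0
    for k in range(n_frames):
        pts, merged = merge_duplicate_points(coords[k])
        merged_total += merged
        traces.append(
            Trace(frame_index=k, time_s=float(times[k]), points=pts, unit=unit)
        )
    if merged_total:
        qc.append(f"render:merged_{merged_total}_quantization_duplicates")

    trace_set = TraceSet(
        flagellum_id=flagellum_id,
        fps=params.fps,
        pixel_size_um=params.pixel_size_um,
        traces=traces,
        condition=condition,
        genotype=genotype,
        qc_flags=qc,
    )
    ground_truth = {
        "flagellum_id": flagellum_id,
        "genotype": genotype,
        "condition": condition,
        "params": params.to_dict(),
    }
    return trace_set, ground_truth


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------


@dataclass
class ScenarioPreset:
    """Named waveform phenotype with its generative parameters."""

    name: str
    genotype: str
    condition: str
    params: WaveParams


def _preset(name, genotype, condition, **overrides) -> ScenarioPreset:
    return ScenarioPreset(name, genotype, condition, WaveParams(**overrides))


#: Phenotype library. Static-curvature ordering encodes the qualitative
#: group contrasts the pipeline must resolve: high-calcium beating of the
#: wild type is strongly asymmetric (kappa0 >> 0), the calcium-sensor point
#: mutant stays symmetric under calcium, the sensor knockout beats only in
#: its proximal half with an elevated distal static bend, and the
#: assembly-mutant flagella are immotile — statically curved when dynein is
#: active, relaxed under vanadate.
PRESETS: dict[str, ScenarioPreset] = {
    p.name: p
    for p in [
        _preset("wt_egta", "WT", "EGTA", kappa0=0.0, amp=0.10, freq_hz=2.0),
        _preset("wt_pca4", "WT", "pCa4", kappa0=0.05, amp=0.10, freq_hz=1.5),
        _preset("e130a_egta", "TgE130A", "EGTA", kappa0=0.0, amp=0.10, freq_hz=2.0),
        _preset("e130a_pca4", "TgE130A", "pCa4", kappa0=0.0, amp=0.10, freq_hz=1.5),
        _preset(
            "calaxin_ko",
            "calaxin-/-",
            "pCa4",
            kappa0=0.02,
            kappa0_distal=0.08,
            kappa0_break_um=15.0,
            amp=0.10,
            amp_envelope="biphasic",
            active_length_um=15.0,
            freq_hz=1.5,
        ),
        _preset(
            "armc4_ko_active",
            "armc4-/-",
            "ATP+ADP",
            kappa0=0.15,
            amp=0.0,
        ),
        _preset(
            "armc4_ko_vanadate",
            "armc4-/-",
            "vanadate",
            kappa0=0.005,
            amp=0.0,
        ),
    ]
}


def make_cohort(
    presets: Sequence[ScenarioPreset | str],
    n_per_group: int,
    seed: int,
    *,
    jitter_rel: float = 0.1,
    overrides: dict | None = None,
) -> list[tuple[TraceSet, dict]]:
    """Render a labeled cohort with per-flagellum biological variability.

    kappa0, amp and freq_hz are each perturbed multiplicatively by
    ``1 + jitter_rel * N(0, 1)`` (clipped at 0.1 to keep parameters valid);
    every flagellum gets a child seed drawn from the cohort RNG, so the
    whole cohort is deterministic given ``seed``. ``overrides`` are applied
    to every preset's params before jitter (e.g. shorter duration for quick
    runs).
    """
    if n_per_group < 1:
        raise InputError("n_per_group must be >= 1")
    if jitter_rel < 0:
        raise InputError("jitter_rel must be >= 0")
    rng = np.random.default_rng(seed)
    out: list[tuple[TraceSet, dict]] = []
    for preset in presets:
        if isinstance(preset, str):
            try:
                preset = PRESETS[preset]
            except KeyError:
                raise InputError(f"unknown preset {preset!r}") from None
        base = preset.params.replace(**(overrides or {}))
        for i in range(n_per_group):
            jit = np.clip(1.0 + jitter_rel * rng.standard_normal(3), 0.1, None)
            child_seed = int(rng.integers(0, 2**31 - 1))
            updates = {
                "kappa0": base.kappa0 * jit[0],
                "amp": base.amp * jit[1],
                "freq_hz": base.freq_hz * jit[2],
                # each recording catches its flagellum at a random beat phase
                "phase0": base.phase0 + float(rng.uniform(0.0, 2.0 * np.pi)),
                "seed": child_seed,
            }
            if base.kappa0_distal is not None:
                updates["kappa0_distal"] = base.kappa0_distal * jit[0]
            params = base.replace(**updates)
            fid = f"{preset.name}_{i:03d}"
            out.append(
                render_trace_set(
                    params,
                    flagellum_id=fid,
                    condition=preset.condition,
                    genotype=preset.genotype,
                )
            )
    return out
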
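"""Run configuration: every tunable of the analysis pipeline in one place.

Defaults: tangent angles sampled every 10 pixels with a 20-pixel tangent
window on 4x-upscaled frames (~0.04 um/px), at least 5 time points per beat
cycle, curvature asymmetry read at 10 um from the head, and significance
called at alpha = 0.05.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import InputError


@dataclass
class RunConfig:
    # acquisition
    fps: float = 100.0
    pixel_size_um: float = 0.04
    # geometry sampling
    window_px: int = 20
    step_px: int = 10
    # beat / cycle selection
    min_frames_per_cycle: int = 5
    probe_fraction: float = 0.5
    snr_threshold: float = 5.0
    amplitude_threshold_rad: float = 0.2
    frequency_method: str = "spectral"
    # decomposition
    asymmetry_position_um: float = 10.0
    curvature_floor: float = 1e-4
    asymmetry_mode: str = "magnitude"  # or "signed"
    shift_to_origin: bool = False
    immotile_frame_seed: int = 0
    # statistics
    alpha: float = 0.05
    equal_var: bool = False  # False -> Welch; True -> pooled Student

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise InputError("fps must be > 0")
        if self.pixel_size_um <= 0:
            raise InputError("pixel_size_um must be > 0")
        if self.window_px <= 0 or self.step_px <= 0:
            raise InputError("window_px and step_px must be > 0")
        if self.min_frames_per_cycle < 1:
            raise InputError("min_frames_per_cycle must be >= 1")
        if not 0.0 < self.probe_fraction < 1.0:
            raise InputError("probe_fraction must lie in (0, 1)")
        if self.frequency_method not in ("spectral", "zero_crossing"):
            raise InputError(f"unknown frequency_method {self.frequency_method!r}")
        if self.asymmetry_mode not in ("magnitude", "signed"):
            raise InputError(f"unknown asymmetry_mode {self.asymmetry_mode!r}")
        if not 0.0 < self.alpha < 1.0:
            raise InputError("alpha must lie in (0, 1)")

    def replace(self, **updates: Any) -> "RunConfig":
        return dataclasses.replace(self, **updates)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(mapping))

    @classmethod
    def from_yaml(cls, source: str | Path | io.TextIOBase) -> "RunConfig":
        if isinstance(source, (str, Path)):
            text = Path(source).read_text()
        else:
            text = source.read()
        data = yaml.safe_load(text)
        if data is None:
            return cls()
        if not isinstance(data, Mapping):
            raise InputError("config file must hold a key-value mapping")
        return cls.from_mapping(data)

    def to_yaml(self, target: str | Path | io.TextIOBase) -> None:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if isinstance(target, (str, Path)):
            Path(target).write_text(text)
        else:
            target.write(text)
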
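"""Reading, validating and writing traced flagellum coordinates.

A *trace* is the ordered head-to-tip point sequence clicked on one video
frame; a :class:`TraceSet` bundles all frames of one flagellum together with
the acquisition metadata (frame rate, pixel size) that must come from a
sidecar config — never guessed from the data.

Coordinates use the image convention (origin top-left, y increasing
downward), matching ImageJ exports, and are treated as 0-based continuous
positions. Point order is head→tip and is never reordered by any operation
in this package.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import imagej_roi
from .errors import InputError

UNIT_PIXEL = "pixel"
UNIT_MICRON = "micron"

#: Minimum number of distinct points for a usable trace (one tangent window
#: of 20 px plus a margin must fit).
MIN_TRACE_POINTS = 21

TRACE_COLUMNS = ["flagellum_id", "frame", "x", "y"]

RESULT_COLUMNS = [
    "flagellum_id",
    "genotype",
    "condition",
    "n_frames_used",
    "basal_curvature_rad_per_um",
    "intercept_rad",
    "asymmetry_index",
    "beat_frequency_hz",
    "qc_flags",
]

#: Sentinel written for undefined numeric values (never blank-as-zero).
NA = "NA"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Trace:
    """Ordered head→tip 2-D point sequence for one flagellum in one frame."""

    frame_index: int
    time_s: float
    points: np.ndarray  # (n, 2) float
    unit: str = UNIT_PIXEL

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise InputError("trace points must form an (n, 2) array")
        if self.points.shape[0] < 2:
            raise InputError("trace needs at least 2 points")
        if not np.all(np.isfinite(self.points)):
            raise InputError("trace points must be finite")
        if self.unit not in (UNIT_PIXEL, UNIT_MICRON):
            raise InputError(f"unknown unit {self.unit!r}")
        if self.frame_index < 0:
            raise InputError("frame_index must be >= 0")
        seg = np.diff(self.points, axis=0)
        if np.any(np.all(seg == 0.0, axis=1)):
            raise InputError(
                "consecutive duplicate points in trace; merge them before "
                "constructing a Trace"
            )

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])


@dataclass
class TraceSet:
    """All traced frames of one flagellum plus acquisition metadata."""

    flagellum_id: str
    fps: float
    pixel_size_um: float
    traces: list[Trace]
    condition: str = ""
    genotype: str = ""
    qc_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise InputError("fps must be > 0")
        if self.pixel_size_um <= 0:
            raise InputError("pixel_size_um must be > 0")
        if not self.traces:
            raise InputError(f"{self.flagellum_id}: trace set holds no traces")
        frames = [t.frame_index for t in self.traces]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise InputError("frame_index must be strictly increasing")
        units = {t.unit for t in self.traces}
        if len(units) != 1:
            raise InputError("all traces in a set must share one unit")

    @property
    def unit(self) -> str:
        return self.traces[0].unit

    @property
    def n_frames(self) -> int:
        return len(self.traces)


@dataclass
class FlagellumResult:
    """Per-flagellum summary of the waveform analysis."""

    flagellum_id: str
    genotype: str
    condition: str
    n_frames_used: int
    basal_curvature: float  # rad/um
    intercept: float  # rad
    asymmetry_index: float | None  # dimensionless >= 1, or undefined
    beat_frequency_hz: float | None
    qc_flags: list[str] = field(default_factory=list)
    # Companion statistic for immotile flagella (mean |kappa| along the
    # analysed frames); not part of the tabular output.
    mean_abs_curvature: float | None = None

    def __post_init__(self) -> None:
        if self.n_frames_used < 1:
            raise InputError("n_frames_used must be >= 1")


# ---------------------------------------------------------------------------
# cleaning helpers
# ---------------------------------------------------------------------------


def merge_duplicate_points(points: np.ndarray) -> tuple[np.ndarray, int]:
    """Drop consecutive duplicate points; returns (cleaned, n_merged).

    Duplicates are a common artifact of manual tracing and of pixel
    quantization; order is preserved.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 2:
        return pts, 0
    keep = np.ones(pts.shape[0], dtype=bool)
    keep[1:] = np.any(np.diff(pts, axis=0) != 0.0, axis=1)
    return pts[keep], int(np.count_nonzero(~keep))


def _build_trace(
    points: np.ndarray,
    frame_index: int,
    fps: float,
    unit: str,
    time_s: float | None = None,
) -> tuple[Trace | None, list[str]]:
    """Clean raw clicked points into a Trace, or None with QC flags."""
    flags: list[str] = []
    pts = np.asarray(points, dtype=float)
    if pts.size == 0 or not np.all(np.isfinite(pts)):
        return None, [f"frame{frame_index}:dropped_nan_coordinates"]
    pts, merged = merge_duplicate_points(pts)
    if merged:
        flags.append(f"frame{frame_index}:merged_{merged}_duplicate_points")
    if pts.shape[0] < MIN_TRACE_POINTS:
        flags.append(
            f"frame{frame_index}:dropped_short_trace_{pts.shape[0]}_points"
        )
        return None, flags
    t = float(frame_index) / fps if time_s is None else float(time_s)
    return Trace(frame_index=int(frame_index), time_s=t, points=pts, unit=unit), flags


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_trace_tables(
    source,
    dialect: str = "csv",
    *,
    fps: float,
    pixel_size_um: float,
    condition: str = "",
    genotype: str = "",
    unit: str = UNIT_PIXEL,
) -> list[TraceSet]:
    """Read a trace table possibly holding several flagella.

    ``dialect`` selects the container: ``csv``/``tsv`` for delimited tables
    with header ``flagellum_id,frame,x,y`` (rows in head→tip point order
    within a frame), or ``roi`` for ImageJ ROI files/zips with one polyline
    per frame named ``<flagellum_id>_<frame>``.

    fps and pixel_size_um are required keyword metadata from the sidecar
    config; they are deliberately never inferred from the data.
    """
    if dialect in ("csv", "tsv"):
        groups = _read_delimited(source, sep="," if dialect == "csv" else "\t")
    elif dialect == "roi":
        groups = _read_roi(source)
    else:
        raise InputError(f"unknown dialect {dialect!r}")

    sets: list[TraceSet] = []
    for fid, frames in groups.items():
        traces: list[Trace] = []
        flags: list[str] = []
        for frame_index in sorted(frames):
            trace, tf = _build_trace(frames[frame_index], frame_index, fps, unit)
            flags.extend(tf)
            if trace is not None:
                traces.append(trace)
        if not traces:
            raise InputError(
                f"flagellum {fid!r}: no frame survived validation "
                f"(flags: {flags})"
            )
        sets.append(
            TraceSet(
                flagellum_id=str(fid),
                fps=fps,
                pixel_size_um=pixel_size_um,
                traces=traces,
                condition=condition,
                genotype=genotype,
                qc_flags=flags,
            )
        )
    return sets


def read_trace_table(source, dialect: str = "csv", **kwargs) -> TraceSet:
    """Read a trace table holding exactly one flagellum. See read_trace_tables."""
    sets = read_trace_tables(source, dialect, **kwargs)
    if len(sets) != 1:
        raise InputError(
            f"expected exactly one flagellum, found {len(sets)}: "
            f"{[s.flagellum_id for s in sets]}; use read_trace_tables"
        )
    return sets[0]


def _read_delimited(source, sep: str) -> dict[str, dict[int, np.ndarray]]:
    try:
        df = pd.read_csv(source, sep=sep, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise InputError("empty trace table") from None
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"trace table lacks columns {missing}")
    if len(df) == 0:
        raise InputError("trace table holds no rows")
    df = df[TRACE_COLUMNS]
    groups: dict[str, dict[int, np.ndarray]] = {}
    # Preserve file order within each (flagellum, frame) group: it is the
    # head→tip click order and must never be re-sorted.
    for (fid, frame), sub in df.groupby(["flagellum_id", "frame"], sort=True):
        pts = sub[["x", "y"]].to_numpy(dtype=float)
        groups.setdefault(str(fid), {})[int(frame)] = pts
    return groups


_ROI_NAME = re.compile(r"^(?P<fid>.+)_(?P<frame>\d+)$")


def _read_roi(source) -> dict[str, dict[int, np.ndarray]]:
    path = Path(source)
    if path.suffix.lower() == ".zip":
        rois = imagej_roi.read_roi_zip(path)
    else:
        name, pts = imagej_roi.read_roi_file(path)
        rois = {name: pts}
    groups: dict[str, dict[int, np.ndarray]] = {}
    for name, pts in rois.items():
        m = _ROI_NAME.match(name)
        if m is None:
            raise InputError(
                f"ROI name {name!r} does not match '<flagellum_id>_<frame>'"
            )
        groups.setdefault(m["fid"], {})[int(m["frame"])] = pts
    if not groups:
        raise InputError("no ROIs found")
    return groups


# ---------------------------------------------------------------------------
# unit conversion
# ---------------------------------------------------------------------------


def to_microns(trace_set: TraceSet) -> TraceSet:
    """Convert a pixel-unit TraceSet to microns; idempotent on micron input."""
    if trace_set.pixel_size_um <= 0:
        raise InputError("pixel_size_um must be > 0")
    if trace_set.unit == UNIT_MICRON:
        return trace_set
    scale = trace_set.pixel_size_um
    traces = [
        Trace(
            frame_index=t.frame_index,
            time_s=t.time_s,
            points=t.points * scale,
            unit=UNIT_MICRON,
        )
        for t in trace_set.traces
    ]
    return TraceSet(
        flagellum_id=trace_set.flagellum_id,
        fps=trace_set.fps,
        pixel_size_um=trace_set.pixel_size_um,
        traces=traces,
        condition=trace_set.condition,
        genotype=trace_set.genotype,
        qc_flags=list(trace_set.qc_flags),
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def _fmt(value: float) -> str:
    # %.12g keeps integers exact and floats reproducible to 12 significant
    # digits, enough for byte-identical reruns and lossless round trips at
    # the declared precision.
    return format(float(value), ".12g")


def write_trace_table(trace_sets: TraceSet | Iterable[TraceSet], stream) -> None:
    """Write trace sets as a CSV with header ``flagellum_id,frame,x,y``."""
    if isinstance(trace_sets, TraceSet):
        trace_sets = [trace_sets]
    close = False
    if isinstance(stream, (str, Path)):
        stream = open(stream, "w", newline="")
        close = True
    try:
        w = csv.writer(stream, lineterminator="\n")
        w.writerow(TRACE_COLUMNS)
        for ts in trace_sets:
            for tr in ts.traces:
                for x, y in tr.points:
                    w.writerow([ts.flagellum_id, tr.frame_index, _fmt(x), _fmt(y)])
    finally:
        if close:
            stream.close()


def write_results(results: Sequence[FlagellumResult], stream) -> None:
    """Write per-flagellum results as CSV, one row per flagellum.

    Undefined values are written as the explicit sentinel ``NA``; qc_flags
    are joined with ``;``. Column order is stable (RESULT_COLUMNS).
    """
    if not results:
        raise InputError("no results to write")
    close = False
    if isinstance(stream, (str, Path)):
        stream = open(stream, "w", newline="")
        close = True
    try:
        w = csv.writer(stream, lineterminator="\n")
        w.writerow(RESULT_COLUMNS)
        for r in results:
            w.writerow(
                [
                    r.flagellum_id,
                    r.genotype,
                    r.condition,
                    r.n_frames_used,
                    _fmt(r.basal_curvature),
                    _fmt(r.intercept),
                    NA if r.asymmetry_index is None else _fmt(r.asymmetry_index),
                    NA if r.beat_frequency_hz is None else _fmt(r.beat_frequency_hz),
                    ";".join(r.qc_flags),
                ]
            )
    finally:
        if close:
            stream.close()


def read_results(stream) -> list[FlagellumResult]:
    """Parse a results CSV written by write_results back into objects."""
    close = False
    if isinstance(stream, (str, Path)):
        stream = open(stream, "r", newline="")
        close = True
    try:
        reader = csv.DictReader(stream)
        if reader.fieldnames is None:
            raise InputError("empty results file")
        missing = [c for c in RESULT_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise InputError(f"results file lacks columns {missing}")
        out: list[FlagellumResult] = []
        for row in reader:
            out.append(
                FlagellumResult(
                    flagellum_id=row["flagellum_id"],
                    genotype=row["genotype"],
                    condition=row["condition"],
                    n_frames_used=int(row["n_frames_used"]),
                    basal_curvature=float(row["basal_curvature_rad_per_um"]),
                    intercept=float(row["intercept_rad"]),
                    asymmetry_index=_parse_opt(row["asymmetry_index"]),
                    beat_frequency_hz=_parse_opt(row["beat_frequency_hz"]),
                    qc_flags=row["qc_flags"].split(";") if row["qc_flags"] else [],
                )
            )
        if not out:
            raise InputError("results file holds no rows")
        return out
    finally:
        if close:
            stream.close()


def _parse_opt(text: str) -> float | None:
    if text == NA or text == "":
        return None
    value = float(text)
    if math.isnan(value):
        return None
    return value


def results_to_frame(results: Sequence[FlagellumResult]) -> pd.DataFrame:
    """Tabulate results for the stats layer; adds a ``group`` label column
    (``genotype:condition``). Undefined values become NaN."""
    rows = []
    for r in results:
        rows.append(
            {
                "flagellum_id": r.flagellum_id,
                "genotype": r.genotype,
                "condition": r.condition,
                "group": f"{r.genotype}:{r.condition}",
                "n_frames_used": r.n_frames_used,
                "basal_curvature": r.basal_curvature,
                "intercept": r.intercept,
                "asymmetry_index": np.nan
                if r.asymmetry_index is None
                else r.asymmetry_index,
                "beat_frequency_hz": np.nan
                if r.beat_frequency_hz is None
                else r.beat_frequency_hz,
            }
        )
    return pd.DataFrame(rows)


def write_roi_traces(trace_set: TraceSet, path: str | Path) -> None:
    """Export a TraceSet as an ImageJ ROI-set zip (one polyline per frame)."""
    rois = {
        f"{trace_set.flagellum_id}_{t.frame_index}": t.points
        for t in trace_set.traces
    }
    imagej_roi.write_roi_zip(path, rois)
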
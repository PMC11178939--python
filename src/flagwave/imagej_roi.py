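"""Minimal ImageJ ``.roi`` codec for polyline ROIs.

Supports exactly what the tracing workflow produces: polyline (segmented
line) ROIs with integer pixel vertices, stored either as a single ``.roi``
file or as a ``.zip`` ROI set whose entry names carry the ROI names. This is
a deliberately small subset of the ImageJ ROI format — enough to round-trip
manual flagellum traces without external dependencies.
"""

from __future__ import annotations

import struct
import zipfile
from pathlib import Path

import numpy as np

from .errors import InputError

_MAGIC = b"Iout"
_VERSION = 227
_TYPE_POLYLINE = 5
_HEADER_SIZE = 64


def encode_polyline(points: np.ndarray) -> bytes:
    """Encode an (n, 2) array of x, y pixel vertices as an ImageJ polyline ROI.

    Coordinates are rounded to integers; the bounding-box offset is stored in
    the header as ImageJ does.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise InputError("polyline needs an (n>=2, 2) coordinate array")
    xi = np.rint(pts[:, 0]).astype(int)
    yi = np.rint(pts[:, 1]).astype(int)
    left, top = int(xi.min()), int(yi.min())
    right, bottom = int(xi.max()) + 1, int(yi.max()) + 1
    n = len(xi)
    header = bytearray(_HEADER_SIZE)
    header[0:4] = _MAGIC
    struct.pack_into(">h", header, 4, _VERSION)
    header[6] = _TYPE_POLYLINE
    struct.pack_into(">hhhh", header, 8, top, left, bottom, right)
    struct.pack_into(">h", header, 16, n)
    body = struct.pack(f">{n}h", *(xi - left)) + struct.pack(f">{n}h", *(yi - top))
    return bytes(header) + body


def decode_polyline(data: bytes) -> np.ndarray:
    """Decode a polyline/freeline/polygon ROI into an (n, 2) float array."""
    if len(data) < _HEADER_SIZE or data[0:4] != _MAGIC:
        raise InputError("not an ImageJ ROI (bad magic)")
    roi_type = data[6]
    if roi_type not in (0, 4, 5, 7, 8):  # polygon, freeline, polyline, freehand, traced
        raise InputError(f"unsupported ROI type {roi_type}; expected a polyline")
    top, left, _bottom, _right = struct.unpack_from(">hhhh", data, 8)
    (n,) = struct.unpack_from(">h", data, 16)
    if n < 2:
        raise InputError("ROI holds fewer than 2 vertices")
    need = _HEADER_SIZE + 4 * n
    if len(data) < need:
        raise InputError("truncated ROI coordinate block")
    xs = np.array(struct.unpack_from(f">{n}h", data, _HEADER_SIZE), dtype=float)
    ys = np.array(struct.unpack_from(f">{n}h", data, _HEADER_SIZE + 2 * n), dtype=float)
    return np.column_stack([xs + left, ys + top])


def read_roi_file(path: str | Path) -> tuple[str, np.ndarray]:
    """Read one ``.roi`` file; the ROI name is the file stem."""
    path = Path(path)
    return path.stem, decode_polyline(path.read_bytes())


def read_roi_zip(path: str | Path) -> dict[str, np.ndarray]:
    """Read an ImageJ ROI-set zip; returns {roi_name: (n, 2) array}."""
    out: dict[str, np.ndarray] = {}
    with zipfile.ZipFile(path) as zf:
        names = [n for n in zf.namelist() if n.lower().endswith(".roi")]
        if not names:
            raise InputError(f"{path}: zip contains no .roi entries")
        for name in sorted(names):
            out[Path(name).stem] = decode_polyline(zf.read(name))
    return out


def write_roi_zip(path: str | Path, rois: dict[str, np.ndarray]) -> None:
    """Write {roi_name: (n, 2) array} as an ImageJ-compatible ROI-set zip."""
    if not rois:
        raise InputError("no ROIs to write")
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for name, pts in rois.items():
            zf.writestr(f"{name}.roi", encode_polyline(pts))
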
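"""File formats and super-resolution rendering.

Localization tables travel as plain CSV in two dialects:

* ``native`` — header ``id,frame,x_nm,y_nm,z_nm,truth_ring``; lossless
  round trips.
* ``thunderstorm`` — ThunderSTORM-style header with ``"x [nm]"``,
  ``"y [nm]"``, ``"z [nm]"`` and ``frame`` columns, as exported by common
  SMLM fitting software.

Dialects are recognized by header match only, never by content heuristics.
Every writer also emits a ``<file>.meta.json`` sidecar with provenance
(software version, optional config hash and seed).

:func:`render_gaussian` converts a localization table into a conventional
super-resolution image by depicting each localization as a unit-integral 2D
Gaussian peak.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, InvalidArgumentError
from .localizations import COLUMNS, LocalizationTable

__all__ = [
    "Image2D",
    "read_localizations",
    "write_localizations",
    "read_trace",
    "write_trace",
    "read_frap_trace",
    "write_frap_trace",
    "read_image",
    "write_image",
    "write_sidecar",
    "render_gaussian",
]

_THUNDERSTORM_MAP = {"x [nm]": "x_nm", "y [nm]": "y_nm", "z [nm]": "z_nm", "frame": "frame"}


@dataclass(frozen=True)
class Image2D:
    """Single-channel image with physical pixel size and nm origin offset.

    Pixel ``(i, j)`` covers the half-open nm square
    ``[origin_x + j*p, origin_x + (j+1)*p) x [origin_y + i*p, origin_y + (i+1)*p)``
    with ``p = pixel_size_nm`` — rows index y, columns index x.
    """

    pixels: np.ndarray
    pixel_size_nm: float
    origin_nm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise InvalidArgumentError("Image2D expects a 2D pixel array")
        if not self.pixel_size_nm > 0:
            raise InvalidArgumentError("pixel_size_nm must be positive")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "origin_nm", (float(self.origin_nm[0]), float(self.origin_nm[1])))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _sniff_dialect(columns) -> str:
    cols = set(columns)
    if {"x_nm", "y_nm"} <= cols:
        return "native"
    if {"x [nm]", "y [nm]"} <= cols:
        return "thunderstorm"
    raise FormatError(
        "unrecognized localization CSV header: need 'x_nm'/'y_nm' (native) or "
        "'x [nm]'/'y [nm]' (thunderstorm)"
    )


def _numeric(df: pd.DataFrame, col: str) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(f"non-numeric value in column {col!r} at data row {row}")
    if vals.isna().any():
        row = int(np.flatnonzero(vals.isna().to_numpy())[0])
        raise FormatError(f"missing value in column {col!r} at data row {row}")
    return vals.to_numpy()


def read_localizations(path, dialect: str = "auto") -> LocalizationTable:
    """Read a localization CSV, validating columns and coordinates.

    Unknown columns are preserved as opaque extras; a missing z column is
    treated as 0 with a warning.  Missing mandatory columns or non-numeric
    coordinates raise :class:`FormatError` naming the offending column/row.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if dialect == "auto":
        dialect = _sniff_dialect(df.columns)
    if dialect == "thunderstorm":
        df = df.rename(columns=_THUNDERSTORM_MAP)
    elif dialect != "native":
        raise InvalidArgumentError(f"unknown dialect {dialect!r}")
    for col in ("x_nm", "y_nm"):
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing mandatory column {col!r}")
    n = len(df)
    data = {
        "x_nm": _numeric(df, "x_nm"),
        "y_nm": _numeric(df, "y_nm"),
    }
    if "z_nm" in df.columns:
        data["z_nm"] = _numeric(df, "z_nm")
    else:
        warnings.warn(f"{path.name}: no z column; treating z as 0", stacklevel=2)
        data["z_nm"] = np.zeros(n)
    data["frame"] = _numeric(df, "frame").astype(np.int64) if "frame" in df.columns else np.ones(n, dtype=np.int64)
    data["id"] = _numeric(df, "id").astype(np.int64) if "id" in df.columns else np.arange(n, dtype=np.int64)
    data["truth_ring"] = (
        _numeric(df, "truth_ring").astype(np.int64) if "truth_ring" in df.columns
        else np.full(n, -1, dtype=np.int64)
    )
    known = set(COLUMNS) | set(_THUNDERSTORM_MAP.values())
    extra_cols = [c for c in df.columns if c not in known]
    extras = df[extra_cols].reset_index(drop=True) if extra_cols else None
    return LocalizationTable(*(data[c] for c in COLUMNS), extras=extras)


def write_localizations(table: LocalizationTable, path, **provenance) -> None:
    """Write the native CSV dialect plus a provenance sidecar."""
    path = Path(path)
    table.to_dataframe().to_csv(path, index=False)
    write_sidecar(path, kind="localizations", n_rows=len(table), **provenance)


def read_trace(path):
    """Read a neurite trace CSV (``vertex,x_nm,y_nm,z_nm``)."""
    from .geometry import NeuriteTrace

    df = pd.read_csv(path)
    for col in ("x_nm", "y_nm", "z_nm"):
        if col not in df.columns:
            raise FormatError(f"trace file missing column {col!r}")
    if "vertex" in df.columns:
        df = df.sort_values("vertex")
    return NeuriteTrace(df[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float))


def write_trace(trace, path, **provenance) -> None:
    path = Path(path)
    v = trace.vertices
    pd.DataFrame(
        {"vertex": np.arange(v.shape[0]), "x_nm": v[:, 0], "y_nm": v[:, 1], "z_nm": v[:, 2]}
    ).to_csv(path, index=False)
    write_sidecar(path, kind="trace", n_vertices=v.shape[0], **provenance)


def read_frap_trace(path, t_bleach_s: float):
    """Read a FRAP CSV (``t_s,roi,reference``); the bleach time is metadata."""
    from .frap import FrapTrace

    df = pd.read_csv(path)
    for col in ("t_s", "roi", "reference"):
        if col not in df.columns:
            raise FormatError(f"FRAP file missing column {col!r}")
    return FrapTrace(df["t_s"].to_numpy(), df["roi"].to_numpy(),
                     df["reference"].to_numpy(), t_bleach_s=t_bleach_s)


def write_frap_trace(trace, path, **provenance) -> None:
    path = Path(path)
    pd.DataFrame({"t_s": trace.t_s, "roi": trace.roi, "reference": trace.reference}).to_csv(
        path, index=False
    )
    write_sidecar(path, kind="frap_trace", t_bleach_s=trace.t_bleach_s, **provenance)


def write_image(image: Image2D, path, **provenance) -> None:
    path = Path(path)
    tifffile.imwrite(path, image.pixels.astype(np.float32))
    write_sidecar(path, kind="image", pixel_size_nm=image.pixel_size_nm,
                  origin_nm=list(image.origin_nm), **provenance)


def read_image(path, pixel_size_nm: float | None = None) -> Image2D:
    """Read a single-channel TIFF; pixel size comes from the sidecar if present."""
    path = Path(path)
    pixels = np.asarray(tifffile.imread(path), dtype=float)
    origin = (0.0, 0.0)
    sidecar = path.with_name(path.name + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        pixel_size_nm = pixel_size_nm or meta.get("pixel_size_nm")
        origin = tuple(meta.get("origin_nm", origin))
    if pixel_size_nm is None:
        pixel_size_nm = 1.0
    return Image2D(pixels, pixel_size_nm=pixel_size_nm, origin_nm=origin)


def write_sidecar(data_path, **meta) -> Path:
    """Emit ``<file>.meta.json`` provenance next to a data file."""
    from . import __version__

    data_path = Path(data_path)
    sidecar = data_path.with_name(data_path.name + ".meta.json")
    payload = {"software": f"mpskel {__version__}", "file": data_path.name}
    payload.update({k: v for k, v in meta.items() if v is not None})
    sidecar.write_text(json.dumps(payload, indent=1, sort_keys=True, default=str))
    return sidecar


def render_gaussian(
    locs,
    pixel_size_nm: float,
    sigma_nm: float,
    *,
    origin_nm: tuple[float, float] | None = None,
    shape: tuple[int, int] | None = None,
    truncate_sigmas: float = 4.0,
) -> Image2D:
    """Render localizations as a sum of unit-integral 2D Gaussian peaks.

    Each localization deposits a pixel-integrated Gaussian of sd ``sigma_nm``
    (truncated beyond ``truncate_sigmas``), so the image integral equals the
    number of localizations to within the truncated tails (< 0.01% at 4
    sigma).  Rendering is linear: the render of a union of tables is the
    pixelwise sum of their renders on a common canvas.
    """
    if not sigma_nm > 0:
        raise InvalidArgumentError("sigma_nm must be positive")
    if not pixel_size_nm > 0:
        raise InvalidArgumentError("pixel_size_nm must be positive")
    pts = np.asarray(getattr(locs, "xyz", locs), dtype=float)
    if pts.size == 0:
        sh = shape or (1, 1)
        return Image2D(np.zeros(sh), pixel_size_nm, origin_nm or (0.0, 0.0))
    x, y = pts[:, 0], pts[:, 1]
    pad = truncate_sigmas * sigma_nm
    if origin_nm is None:
        origin_nm = (float(x.min() - pad), float(y.min() - pad))
    if shape is None:
        nx = int(np.ceil((x.max() + pad - origin_nm[0]) / pixel_size_nm)) + 1
        ny = int(np.ceil((y.max() + pad - origin_nm[1]) / pixel_size_nm)) + 1
        shape = (ny, nx)
    img = np.zeros(shape)
    ny, nx = shape
    from scipy.special import erf

    inv = 1.0 / (np.sqrt(2.0) * sigma_nm)
    half_w = int(np.ceil(pad / pixel_size_nm)) + 1
    jc = ((x - origin_nm[0]) / pixel_size_nm).astype(int)
    ic = ((y - origin_nm[1]) / pixel_size_nm).astype(int)
    for k in range(pts.shape[0]):
        j0, j1 = max(jc[k] - half_w, 0), min(jc[k] + half_w + 1, nx)
        i0, i1 = max(ic[k] - half_w, 0), min(ic[k] + half_w + 1, ny)
        if j0 >= j1 or i0 >= i1:
            continue
        ex = origin_nm[0] + np.arange(j0, j1 + 1) * pixel_size_nm  # pixel edges, x
        ey = origin_nm[1] + np.arange(i0, i1 + 1) * pixel_size_nm
        wx = 0.5 * np.diff(erf((ex - x[k]) * inv))
        wy = 0.5 * np.diff(erf((ey - y[k]) * inv))
        img[i0:i1, j0:j1] += np.outer(wy, wx)
    return Image2D(img, pixel_size_nm, origin_nm)
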
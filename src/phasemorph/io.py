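"""Reading and writing phase/gradient rasters and morphometry reports.

Rasters travel as single-channel 32-bit float TIFF (radians) or plain CSV
matrices.  The pixel calibration and map semantics live in a JSON sidecar
(``<stem>.meta.json``) written next to the raster; reading an external map
without a sidecar requires an explicit pixel pitch, since a raster alone
does not determine physical scale.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .gradients import GradientMap
from .jumps import DistanceReport, ErrorStats
from .model import GridSpec, PhaseMap

__all__ = [
    "CalibrationError",
    "sidecar_path",
    "write_map",
    "read_phase_map",
    "read_gradient_map",
    "write_report_csv",
    "write_report_json",
]


class CalibrationError(ValueError):
    """Pixel calibration is required but was not supplied or found."""


def sidecar_path(path: Path) -> Path:
    """Metadata sidecar next to a raster file: ``<stem>.meta.json``."""
    path = Path(path)
    return path.with_name(path.stem + ".meta.json")


def _metadata(obj: PhaseMap | GradientMap) -> dict:
    meta = {
        "kind": "gradient" if isinstance(obj, GradientMap) else "phase",
        "dx_um": obj.grid.dx,
        "dy_um": obj.grid.dy,
        "width_um": obj.grid.width,
        "height_um": obj.grid.height,
        "nx": obj.grid.nx,
        "ny": obj.grid.ny,
        "units": "rad",
    }
    if isinstance(obj, GradientMap):
        meta["axis"] = obj.axis
        meta["squared"] = obj.squared
        meta["units"] = "rad2.um-2" if obj.squared else "rad.um-1"
    return meta


def write_map(path, obj: PhaseMap | GradientMap) -> Path:
    """Write a map as float32 TIFF (``.tif``/``.tiff``) or CSV (``.csv``),
    plus its JSON metadata sidecar.  Returns the raster path."""
    path = Path(path)
    values = obj.values.astype(np.float32)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, values)
    elif path.suffix.lower() == ".csv":
        np.savetxt(path, obj.values, delimiter=",", fmt="%.9g")
    else:
        raise ValueError(f"unsupported raster format: {path.suffix!r}")
    sidecar_path(path).write_text(json.dumps(_metadata(obj), indent=2) + "\n")
    return path


def _read_values(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path), dtype=float)
    if path.suffix.lower() == ".csv":
        return np.atleast_2d(np.loadtxt(path, delimiter=",", dtype=float))
    raise ValueError(f"unsupported raster format: {path.suffix!r}")


def _grid_for(path: Path, shape: tuple[int, int], pixel_um, meta: dict | None) -> GridSpec:
    ny, nx = shape
    if pixel_um is not None:
        dx, dy = (pixel_um, pixel_um) if np.isscalar(pixel_um) else pixel_um
        return GridSpec(width=nx * dx, height=ny * dy, nx=nx, ny=ny)
    if meta is not None:
        return GridSpec(
            width=nx * meta["dx_um"], height=ny * meta["dy_um"], nx=nx, ny=ny
        )
    raise CalibrationError(
        f"no pixel calibration for {path}: supply pixel_um explicitly or "
        f"provide a {sidecar_path(path).name} sidecar"
    )


def _read_meta(path: Path) -> dict | None:
    sp = sidecar_path(path)
    if sp.exists():
        return json.loads(sp.read_text())
    return None


def read_phase_map(path, pixel_um=None) -> PhaseMap:
    """Read a phase raster (TIFF or CSV).

    ``pixel_um`` (a scalar or ``(dx, dy)``, in um) overrides or replaces
    the sidecar calibration; without either a :class:`CalibrationError` is
    raised.
    """
    path = Path(path)
    values = _read_values(path)
    grid = _grid_for(path, values.shape, pixel_um, _read_meta(path))
    return PhaseMap(values=values, grid=grid)


def read_gradient_map(path, pixel_um=None) -> GradientMap:
    """Read a gradient raster; axis and squared flags come from the
    sidecar (defaulting to an unsquared x-gradient)."""
    path = Path(path)
    values = _read_values(path)
    meta = _read_meta(path)
    grid = _grid_for(path, values.shape, pixel_um, meta)
    axis = (meta or {}).get("axis", "x")
    squared = bool((meta or {}).get("squared", False))
    return GradientMap(values=values, grid=grid, axis=axis, squared=squared)


def report_frame(report: DistanceReport, stats: ErrorStats | None = None) -> pd.DataFrame:
    """Tabulate a distance report (one row per labelled separation),
    optionally joined with per-row error statistics."""
    frame = pd.DataFrame(report.to_records())
    if stats is not None:
        frame["set_um"] = stats.set_um
        frame["abs_err_um"] = [round(e, 3) for e in stats.abs_errors_um]
        frame["rel_err_pct"] = [round(100 * e, 2) for e in stats.rel_errors]
    return frame


def write_report_csv(path, report: DistanceReport, stats: ErrorStats | None = None) -> Path:
    path = Path(path)
    report_frame(report, stats).to_csv(path, index=False)
    return path


def write_report_json(path, report: DistanceReport, stats: ErrorStats | None = None) -> Path:
    path = Path(path)
    payload: dict = {"step_um": report.step_um, "rows": report.to_records()}
    if stats is not None:
        payload["error_stats"] = stats.to_dict()
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path
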
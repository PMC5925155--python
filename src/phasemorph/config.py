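"""Structured run configuration: YAML schema, validation and defaults.

A run is described by a nested-sphere model, a raster, optional noise,
the profile geometries to analyse, the detector settings and optional
ground-truth separations.  Unknown keys are rejected with the offending
key named, so typos never silently fall back to defaults.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .gradients import ColumnLine, ObliqueLine, RowLine
from .model import CellModel, GridSpec, NoiseSpec, SphereComponent

__all__ = ["RunConfig", "ConfigError", "load_config", "config_to_dict", "config_hash"]

DEFAULT_WAVELENGTH_UM = 0.6328
DEFAULT_MEDIUM_INDEX = 1.33
DEFAULT_THRESHOLD_FRACTION = 0.5
DEFAULT_MERGE_GAP = 3


class ConfigError(ValueError):
    """Configuration file violates the schema."""


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration."""

    model: CellModel
    grid: GridSpec
    noise: NoiseSpec | None = None
    profiles: tuple = ()
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION
    merge_gap: int = DEFAULT_MERGE_GAP
    truth_um: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.threshold_fraction < 1:
            raise ConfigError(
                f"threshold_fraction must be in (0, 1), got {self.threshold_fraction}"
            )


def _require_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


def _sphere(section: dict, where: str) -> SphereComponent:
    _require_keys(section, {"center", "radius", "index"}, where)
    for key in ("center", "radius", "index"):
        if key not in section:
            raise ConfigError(f"missing key {key!r} in {where}")
    return SphereComponent(
        center=tuple(float(v) for v in section["center"]),
        radius=float(section["radius"]),
        refractive_index=float(section["index"]),
    )


def _grid(section: dict) -> GridSpec:
    _require_keys(section, {"width_um", "height_um", "nx", "ny"}, "grid")
    try:
        return GridSpec(
            width=float(section["width_um"]),
            height=float(section["height_um"]),
            nx=int(section["nx"]),
            ny=int(section["ny"]),
        )
    except KeyError as exc:
        raise ConfigError(f"missing key {exc.args[0]!r} in grid") from exc


def _profile(entry: dict, grid: GridSpec, where: str):
    _require_keys(
        entry, {"kind", "index", "y_um", "x_um", "start", "end"}, where
    )
    kind = entry.get("kind")
    if kind == "row":
        if "index" in entry:
            idx = int(entry["index"])
        elif "y_um" in entry:
            idx = grid.nearest_row(float(entry["y_um"]))
        else:
            raise ConfigError(f"{where}: row profile needs 'index' or 'y_um'")
        if not 0 <= idx < grid.ny:
            raise ConfigError(f"{where}: row {idx} outside raster of {grid.ny} rows")
        return RowLine(idx)
    if kind == "column":
        if "index" in entry:
            idx = int(entry["index"])
        elif "x_um" in entry:
            idx = grid.nearest_col(float(entry["x_um"]))
        else:
            raise ConfigError(f"{where}: column profile needs 'index' or 'x_um'")
        if not 0 <= idx < grid.nx:
            raise ConfigError(f"{where}: column {idx} outside raster of {grid.nx} columns")
        return ColumnLine(idx)
    if kind == "oblique":
        try:
            start = tuple(int(v) for v in entry["start"])
            end = tuple(int(v) for v in entry["end"])
        except KeyError as exc:
            raise ConfigError(f"{where}: oblique profile needs 'start' and 'end'") from exc
        for r, c in (start, end):
            if not (0 <= r < grid.ny and 0 <= c < grid.nx):
                raise ConfigError(f"{where}: endpoint ({r}, {c}) outside raster")
        return ObliqueLine(start, end)
    raise ConfigError(f"{where}: kind must be 'row', 'column' or 'oblique', got {kind!r}")


_TOP_KEYS = {
    "wavelength_um",
    "medium_index",
    "body",
    "inclusions",
    "grid",
    "noise",
    "profiles",
    "threshold_fraction",
    "merge_gap",
    "truth_um",
}


def parse_config(data: dict) -> RunConfig:
    """Build a validated :class:`RunConfig` from a plain mapping."""
    if not isinstance(data, dict):
        raise ConfigError("configuration must be a mapping")
    _require_keys(data, _TOP_KEYS, "top level")
    if "grid" not in data:
        raise ConfigError("missing required section 'grid'")
    if "body" not in data:
        raise ConfigError("missing required section 'body'")
    grid = _grid(data["grid"])
    body = _sphere(data["body"], "body")
    inclusions = tuple(
        _sphere(entry, f"inclusions[{k}]")
        for k, entry in enumerate(data.get("inclusions") or [])
    )
    model = CellModel(
        body=body,
        inclusions=inclusions,
        medium_index=float(data.get("medium_index", DEFAULT_MEDIUM_INDEX)),
        wavelength=float(data.get("wavelength_um", DEFAULT_WAVELENGTH_UM)),
    )
    noise = None
    if data.get("noise") is not None:
        _require_keys(data["noise"], {"snr_db", "seed"}, "noise")
        noise = NoiseSpec(
            snr_db=float(data["noise"]["snr_db"]),
            seed=int(data["noise"].get("seed", 0)),
        )
    profiles = tuple(
        _profile(entry, grid, f"profiles[{k}]")
        for k, entry in enumerate(data.get("profiles") or [])
    )
    truth = data.get("truth_um")
    return RunConfig(
        model=model,
        grid=grid,
        noise=noise,
        profiles=profiles,
        threshold_fraction=float(
            data.get("threshold_fraction", DEFAULT_THRESHOLD_FRACTION)
        ),
        merge_gap=int(data.get("merge_gap", DEFAULT_MERGE_GAP)),
        truth_um=tuple(float(v) for v in truth) if truth is not None else None,
    )


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    with path.open() as handle:
        data = yaml.safe_load(handle)
    try:
        return parse_config(data)
    except ConfigError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def config_to_dict(config: RunConfig) -> dict:
    """Serialize a RunConfig back to the plain YAML schema."""

    def sphere(s: SphereComponent) -> dict:
        return {
            "center": list(s.center),
            "radius": s.radius,
            "index": s.refractive_index,
        }

    def line(geom) -> dict:
        if isinstance(geom, RowLine):
            return {"kind": "row", "index": geom.row}
        if isinstance(geom, ColumnLine):
            return {"kind": "column", "index": geom.col}
        return {"kind": "oblique", "start": list(geom.start), "end": list(geom.end)}

    out: dict = {
        "wavelength_um": config.model.wavelength,
        "medium_index": config.model.medium_index,
        "body": sphere(config.model.body),
        "inclusions": [sphere(s) for s in config.model.inclusions],
        "grid": {
            "width_um": config.grid.width,
            "height_um": config.grid.height,
            "nx": config.grid.nx,
            "ny": config.grid.ny,
        },
        "profiles": [line(g) for g in config.profiles],
        "threshold_fraction": config.threshold_fraction,
        "merge_gap": config.merge_gap,
    }
    if config.noise is not None:
        out["noise"] = {"snr_db": config.noise.snr_db, "seed": config.noise.seed}
    if config.truth_um is not None:
        out["truth_um"] = list(config.truth_um)
    return out


def config_hash(config: RunConfig) -> str:
    """Stable SHA-256 of the canonical configuration serialization."""
    payload = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()
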
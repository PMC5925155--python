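"""End-to-end pipeline: simulate, analyse, report, and fixture generation.

``run_simulate`` renders (and optionally noises) the phantom's phase map;
``run_analyze`` takes a rendered bundle, a run configuration or an
external phase raster and carries it through gradient computation, jump
detection, pairing and the physical distance report.  Every bundle records
the seed, configuration hash and package version needed to reproduce it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import __version__
from .config import RunConfig, config_hash, config_to_dict
from .gradients import (
    ColumnLine,
    GradientMap,
    LineProfile,
    ObliqueLine,
    RowLine,
    extract_profile,
    forward_diff_gradient,
    modulus_squared,
)
from .io import read_phase_map, write_map, write_report_csv, write_report_json
from .jumps import (
    DistanceReport,
    ErrorStats,
    JumpPairSet,
    JumpPoint,
    PairingError,
    build_distance_report,
    detect_jumps,
    diameter_error_stats,
    pair_jumps,
)
from .model import (
    CellModel,
    GridSpec,
    NoiseSpec,
    PhaseMap,
    SphereComponent,
    add_gaussian_noise,
    render_phase_map,
)

__all__ = [
    "ProfileResult",
    "AnalysisBundle",
    "phase_center",
    "run_simulate",
    "run_analyze",
    "make_fixture",
    "FIXTURE_NAMES",
]

log = logging.getLogger("phasemorph")


@dataclass(frozen=True)
class ProfileResult:
    """Analysis outcome for one traversal geometry."""

    geometry: object
    profile: LineProfile
    jumps: tuple[JumpPoint, ...]
    pairs: JumpPairSet | None
    report: DistanceReport | None
    pairing_error: str | None = None


@dataclass
class AnalysisBundle:
    """Everything produced by a run, with reproducibility metadata."""

    config: RunConfig | None
    phase: PhaseMap
    phase_noisy: PhaseMap | None = None
    gradient_x: GradientMap | None = None
    gradient_y: GradientMap | None = None
    gradient_sq: GradientMap | None = None
    results: tuple[ProfileResult, ...] = ()
    error_stats: ErrorStats | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def analysis_phase(self) -> PhaseMap:
        """The map the analysis stage runs on (noisy variant if present)."""
        return self.phase_noisy if self.phase_noisy is not None else self.phase


def phase_center(pmap: PhaseMap, median_size: int = 3) -> tuple[int, int]:
    """(row, col) of the phase centre: argmax of the median-filtered map,
    ties resolved to the lowest row-major index."""
    smoothed = ndimage.median_filter(pmap.values, size=median_size)
    return tuple(np.unravel_index(int(np.argmax(smoothed)), smoothed.shape))


def _bundle_metadata(config: RunConfig | None, extra: dict | None = None) -> dict:
    meta = {
        "package": "phasemorph",
        "version": __version__,
        "numpy_version": np.__version__,
    }
    if config is not None:
        meta["config_hash"] = config_hash(config)
        meta["seed"] = config.noise.seed if config.noise is not None else None
        meta["snr_db"] = config.noise.snr_db if config.noise is not None else None
    if extra:
        meta.update(extra)
    return meta


def run_simulate(config: RunConfig, outdir=None) -> AnalysisBundle:
    """Render the configured phantom (phase stage only).

    Writes ``phase.tif`` (plus ``phase_noisy.tif`` when noise is
    configured) and ``bundle.json`` under ``outdir`` when given.
    """
    phase = render_phase_map(config.model, config.grid)
    noisy = add_gaussian_noise(phase, config.noise) if config.noise is not None else None
    bundle = AnalysisBundle(
        config=config,
        phase=phase,
        phase_noisy=noisy,
        metadata=_bundle_metadata(config),
    )
    log.info(
        "simulated phase map %dx%d (config %s, seed %s)",
        config.grid.ny,
        config.grid.nx,
        bundle.metadata.get("config_hash", "-")[:12],
        bundle.metadata.get("seed"),
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_map(outdir / "phase.tif", phase)
        if noisy is not None:
            write_map(outdir / "phase_noisy.tif", noisy)
        (outdir / "bundle.json").write_text(
            json.dumps(
                {"metadata": bundle.metadata, "config": config_to_dict(config)},
                indent=2,
            )
            + "\n"
        )
    return bundle


def _gradient_for(geometry, gx: GradientMap, gy: GradientMap) -> GradientMap:
    """Gradient component along the traversal direction of ``geometry``."""
    if isinstance(geometry, RowLine):
        return gx
    if isinstance(geometry, ColumnLine):
        return gy
    (r0, c0), (r1, c1) = geometry.start, geometry.end
    return gx if abs(c1 - c0) >= abs(r1 - r0) else gy


def run_analyze(
    source,
    *,
    outdir=None,
    profiles=None,
    threshold_fraction: float | None = None,
    merge_gap: int | None = None,
    truth_um=None,
    pixel_um=None,
) -> AnalysisBundle:
    """Run the gradient -> jump -> distance pipeline.

    Parameters
    ----------
    source : RunConfig | AnalysisBundle | path-like
        A configuration (simulated first), an already-simulated bundle, or
        an external phase raster (TIFF/CSV; needs ``pixel_um`` or a
        metadata sidecar).
    profiles : sequence of line geometries, optional
        Defaults to the row and the column through the phase centre.
    truth_um : sequence of float, optional
        Ground-truth separations for the first profile's report rows.

    Notes
    -----
    When the source carries a noisy phase variant the analysis runs on it
    (that is the point of the noise experiment); the noiseless map stays
    in the bundle for reference.
    """
    if isinstance(source, RunConfig):
        bundle = run_simulate(source, outdir=None)
    elif isinstance(source, AnalysisBundle):
        bundle = source
    else:
        bundle = AnalysisBundle(
            config=None,
            phase=read_phase_map(source, pixel_um=pixel_um),
            metadata=_bundle_metadata(None, {"source": str(source)}),
        )
    config = bundle.config
    if threshold_fraction is None:
        threshold_fraction = config.threshold_fraction if config else 0.5
    if merge_gap is None:
        merge_gap = config.merge_gap if config else 3
    if truth_um is None and config is not None:
        truth_um = config.truth_um
    if profiles is None and config is not None and config.profiles:
        profiles = config.profiles

    target = bundle.analysis_phase
    gx = forward_diff_gradient(target, "x")
    gy = forward_diff_gradient(target, "y")
    sq = modulus_squared(gx, gy)
    if profiles is None:
        row, col = phase_center(target)
        profiles = (RowLine(row), ColumnLine(col))

    results = []
    for geometry in profiles:
        gmap = _gradient_for(geometry, gx, gy)
        profile = extract_profile(gmap, geometry)
        jumps = detect_jumps(profile, threshold_fraction, merge_gap=merge_gap)
        pairs = report = err = None
        try:
            if jumps:
                pairs = pair_jumps(jumps)
                report = build_distance_report(pairs, profile.step_um)
        except PairingError as exc:
            err = str(exc)
            log.warning("pairing failed for %s: %s", geometry, exc)
        results.append(
            ProfileResult(
                geometry=geometry,
                profile=profile,
                jumps=tuple(jumps),
                pairs=pairs,
                report=report,
                pairing_error=err,
            )
        )

    stats = None
    if truth_um is not None:
        for res in results:
            if res.report is not None and len(res.report.rows) == len(truth_um):
                stats = diameter_error_stats(res.report, list(truth_um))
                break

    bundle.gradient_x, bundle.gradient_y, bundle.gradient_sq = gx, gy, sq
    bundle.results = tuple(results)
    bundle.error_stats = stats
    bundle.metadata.setdefault("threshold_fraction", threshold_fraction)
    bundle.metadata.setdefault("merge_gap", merge_gap)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_map(outdir / "phase.tif", bundle.phase)
        if bundle.phase_noisy is not None:
            write_map(outdir / "phase_noisy.tif", bundle.phase_noisy)
        write_map(outdir / "gradient_x.tif", gx)
        write_map(outdir / "gradient_y.tif", gy)
        write_map(outdir / "gradient_sq.tif", sq)
        for k, res in enumerate(results):
            if res.report is not None:
                row_stats = stats if (stats and res.report is results[0].report) else None
                write_report_csv(outdir / f"report_{k}.csv", res.report, row_stats)
                write_report_json(outdir / f"report_{k}.json", res.report, row_stats)
        payload = {"metadata": bundle.metadata}
        if config is not None:
            payload["config"] = config_to_dict(config)
        (outdir / "bundle.json").write_text(json.dumps(payload, indent=2) + "\n")
    return bundle


# ---------------------------------------------------------------------------
# Fixtures

FIXTURE_NAMES = ("nucleated_cell", "body_only", "bead_like", "offcenter_line")


def _fixture_config(name: str) -> dict:
    cell = {
        "wavelength_um": 0.6328,
        "medium_index": 1.33,
        "body": {"center": [0.0, 0.0, 0.0], "radius": 6.0, "index": 1.37},
        "inclusions": [
            {"center": [3.0, 0.0, 0.0], "radius": 2.5, "index": 1.45}
        ],
        "grid": {"width_um": 15.0, "height_um": 15.0, "nx": 255, "ny": 255},
        "threshold_fraction": 0.5,
        "merge_gap": 3,
    }
    if name == "nucleated_cell":
        cfg = dict(cell)
        cfg["profiles"] = [
            {"kind": "row", "y_um": 0.0},
            {"kind": "column", "x_um": 0.0},
        ]
        cfg["truth_um"] = [12.0, 5.0, 6.5, 0.5]
        return cfg
    if name == "body_only":
        cfg = dict(cell)
        cfg["inclusions"] = []
        cfg["profiles"] = [
            {"kind": "row", "y_um": 0.0},
            {"kind": "column", "x_um": 0.0},
        ]
        cfg["truth_um"] = [12.0]
        return cfg
    if name == "bead_like":
        # a 50 um polystyrene-like bead in water, coarser field of view
        return {
            "wavelength_um": 0.633,
            "medium_index": 1.33,
            "body": {"center": [0.0, 0.0, 0.0], "radius": 25.0, "index": 1.59},
            "inclusions": [],
            "grid": {"width_um": 60.0, "height_um": 60.0, "nx": 255, "ny": 255},
            "profiles": [
                {"kind": "row", "y_um": 0.0},
                {"kind": "column", "x_um": 0.0},
            ],
            "threshold_fraction": 0.5,
            "merge_gap": 3,
            "truth_um": [50.0],
        }
    if name == "offcenter_line":
        cfg = dict(cell)
        cfg["profiles"] = [{"kind": "row", "y_um": 2.0}]
        # chords of body and nucleus along y = 2, plus edge gaps
        cfg["truth_um"] = [11.314, 3.0, 7.157, 1.157]
        return cfg
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


def make_fixture(name: str, outdir) -> dict[str, Path]:
    """Write a named fixture: its YAML configuration plus a snapshot of the
    distance report the pipeline currently produces for it."""
    import yaml as _yaml

    cfg_dict = _fixture_config(name)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_path = outdir / f"{name}.yaml"
    cfg_path.write_text(_yaml.safe_dump(cfg_dict, sort_keys=False))

    from .config import parse_config

    bundle = run_analyze(parse_config(cfg_dict))
    paths = {"config": cfg_path}
    first = next((r for r in bundle.results if r.report is not None), None)
    if first is not None:
        snap = outdir / f"{name}_report.csv"
        write_report_csv(snap, first.report, bundle.error_stats)
        paths["report"] = snap
    return paths
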
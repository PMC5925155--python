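"""Nested-sphere cell phantom and its quantitative phase map.

A transparent, nucleated cell immersed in medium of refractive index
``n_m`` is modelled as a large sphere (cytoplasm, index ``n1``) containing
smaller spheres (nucleus or other organelles, index ``n2``).  For plane
illumination along the optical (z) axis the accumulated phase delay at an
in-plane point is proportional to the optical path difference

    phi(x, y) = (2 pi / lambda) * sum_k (n_k - n_enclosing) * chord_k(x, y)

where ``chord = 2 * sqrt(R**2 - d**2)`` is the geometric path length of the
axial ray through a sphere of radius ``R`` at in-plane distance ``d`` from
its centre.  The phase map is rendered on a calibrated pixel raster and can
be corrupted with white Gaussian noise at a prescribed SNR to study the
robustness of downstream boundary detection.

All lengths are micrometres, phase is in radians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridSpec",
    "SphereComponent",
    "CellModel",
    "PhaseMap",
    "NoiseSpec",
    "ModelGeometryError",
    "BoundaryGradientError",
    "ZeroSignalError",
    "phase_at",
    "render_phase_map",
    "analytic_gradient_profile",
    "add_gaussian_noise",
    "nucleated_cell_model",
    "nucleated_cell_grid",
]


class ModelGeometryError(ValueError):
    """A sphere component violates the nesting/validity constraints."""


class BoundaryGradientError(ArithmeticError):
    """The closed-form lateral gradient is undefined exactly on a sphere
    boundary, where the chord derivative diverges."""


class ZeroSignalError(ValueError):
    """SNR-referenced noise cannot be defined for an all-zero map."""


@dataclass(frozen=True)
class GridSpec:
    """Calibrated raster geometry.

    The field of view of physical extent ``width x height`` (um) is centred
    on the origin and sampled at pixel centres: column ``i`` (0-based) maps
    to ``x_i = -width/2 + (i + 1/2) * dx`` with ``dx = width / nx``, and
    likewise for rows.  Row index grows with y.

    Parameters
    ----------
    width, height : float
        Physical extents in x and y (um).
    nx, ny : int
        Pixel counts along x and y (each at least 2).
    """

    width: float
    height: float
    nx: int
    ny: int

    def __post_init__(self) -> None:
        if self.nx < 2 or self.ny < 2:
            raise ValueError(f"grid needs nx, ny >= 2, got {self.nx} x {self.ny}")
        if not (self.width > 0 and self.height > 0):
            raise ValueError("grid extents must be positive")

    @property
    def dx(self) -> float:
        """Pixel pitch along x (um)."""
        return self.width / self.nx

    @property
    def dy(self) -> float:
        """Pixel pitch along y (um)."""
        return self.height / self.ny

    def pitch(self, axis: str) -> float:
        """Pixel pitch (um) along ``'x'`` or ``'y'``."""
        if axis == "x":
            return self.dx
        if axis == "y":
            return self.dy
        raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")

    def x_coords(self) -> np.ndarray:
        """Physical x coordinate (um) of every pixel-column centre.

        Computed as ``(i + 1/2 - nx/2) * dx`` (identical to ``-width/2 +
        (i + 1/2) dx``) so mirrored indices give exactly negated
        coordinates in floating point.
        """
        return (np.arange(self.nx) + 0.5 - self.nx / 2) * self.dx

    def y_coords(self) -> np.ndarray:
        """Physical y coordinate (um) of every pixel-row centre."""
        return (np.arange(self.ny) + 0.5 - self.ny / 2) * self.dy

    def nearest_col(self, x: float) -> int:
        """Index of the pixel column whose centre is closest to ``x``."""
        i = int(round(x / self.dx + self.nx / 2 - 0.5))
        if not 0 <= i < self.nx:
            raise ValueError(f"x = {x} um lies outside the raster")
        return i

    def nearest_row(self, y: float) -> int:
        """Index of the pixel row whose centre is closest to ``y``."""
        j = int(round(y / self.dy + self.ny / 2 - 0.5))
        if not 0 <= j < self.ny:
            raise ValueError(f"y = {y} um lies outside the raster")
        return j


@dataclass(frozen=True)
class SphereComponent:
    """A homogeneous sphere: centre (x, y, z) in um, radius in um, and
    refractive index (> 1)."""

    center: tuple[float, float, float]
    radius: float
    refractive_index: float

    def __post_init__(self) -> None:
        if len(self.center) == 2:  # accept (x, y), z defaults to 0
            object.__setattr__(self, "center", (*self.center, 0.0))
        if len(self.center) != 3:
            raise ValueError("center must be (x, y) or (x, y, z)")
        if not self.radius > 0:
            raise ModelGeometryError(f"radius must be > 0, got {self.radius}")
        if not self.refractive_index > 1:
            raise ModelGeometryError(
                f"refractive index must be > 1, got {self.refractive_index}"
            )


@dataclass(frozen=True)
class CellModel:
    """Nested-sphere phantom of a (possibly nucleated) cell.

    Parameters
    ----------
    body : SphereComponent
        The outer sphere (cytoplasm).
    inclusions : tuple of SphereComponent
        Inner spheres (nucleus, organelles).  Each inclusion's projected
        disc must lie entirely within the body's projected disc so the
        additive chord decomposition of the phase is valid.
    medium_index : float
        Refractive index of the surrounding medium (> 1).
    wavelength : float
        Illumination wavelength (um).
    """

    body: SphereComponent
    inclusions: tuple[SphereComponent, ...] = field(default_factory=tuple)
    medium_index: float = 1.33
    wavelength: float = 0.6328

    def __post_init__(self) -> None:
        object.__setattr__(self, "inclusions", tuple(self.inclusions))
        if not self.medium_index > 1:
            raise ModelGeometryError(
                f"medium index must be > 1, got {self.medium_index}"
            )
        if not self.wavelength > 0:
            raise ModelGeometryError(f"wavelength must be > 0, got {self.wavelength}")
        bx, by, _ = self.body.center
        for k, inc in enumerate(self.inclusions):
            ix, iy, _ = inc.center
            if math.hypot(ix - bx, iy - by) + inc.radius > self.body.radius + 1e-12:
                raise ModelGeometryError(
                    f"inclusion {k} (centre ({ix}, {iy}), radius {inc.radius}) "
                    f"is not nested inside the body disc (radius "
                    f"{self.body.radius} at ({bx}, {by}))"
                )

    @property
    def components(self) -> tuple[tuple[SphereComponent, float], ...]:
        """(component, index contrast) pairs: the body against the medium,
        each inclusion against the body."""
        out = [(self.body, self.body.refractive_index - self.medium_index)]
        out.extend(
            (inc, inc.refractive_index - self.body.refractive_index)
            for inc in self.inclusions
        )
        return tuple(out)


@dataclass(frozen=True)
class NoiseSpec:
    """White Gaussian noise prescription at a given SNR.

    ``snr_db`` is 10*log10(P_signal / P_noise) with P_signal the mean
    squared phase over the full image.  ``seed`` fixes the realization
    exactly: equal seeds give bit-identical noise.
    """

    snr_db: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not math.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")


@dataclass(frozen=True)
class PhaseMap:
    """A 2D phase-shift field (radians) bound to its raster geometry.

    ``values`` has shape ``(ny, nx)``; row index follows y, column index
    follows x, consistent with :class:`GridSpec`.
    """

    values: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (self.grid.ny, self.grid.nx):
            raise ValueError(
                f"values shape {v.shape} does not match grid "
                f"({self.grid.ny}, {self.grid.nx})"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("phase values must be finite")


def _chords(model: CellModel, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Stacked contrast-weighted chord lengths, summed over components."""
    total = np.zeros(np.broadcast(x, y).shape)
    for comp, contrast in model.components:
        cx, cy, _ = comp.center
        # sum the squared in-plane distance before subtracting so points
        # exactly on the circle give a radicand of exactly zero
        d2 = (x - cx) ** 2 + (y - cy) ** 2
        rad2 = comp.radius**2 - d2
        total += contrast * 2.0 * np.sqrt(np.maximum(rad2, 0.0))
    return total


def phase_at(model: CellModel, x, y):
    """Phase shift (rad) of the phantom at in-plane point(s) ``(x, y)``.

    Exactly zero outside the body's projected disc; vectorised over
    array-valued ``x``/``y``.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    out = (2.0 * np.pi / model.wavelength) * _chords(model, xa, ya)
    if out.ndim == 0:
        return float(out)
    return out


def render_phase_map(model: CellModel, grid: GridSpec) -> PhaseMap:
    """Render the phantom's phase map at every pixel centre of ``grid``.

    Deterministic; the chord formula is evaluated directly per pixel
    centre with no supersampling.
    """
    X, Y = np.meshgrid(grid.x_coords(), grid.y_coords())
    return PhaseMap(values=phase_at(model, X, Y), grid=grid)


def analytic_gradient_profile(model: CellModel, x, y: float = 0.0):
    """Closed-form lateral phase derivative d(phi)/dx (rad/um) at ``(x, y)``.

    Each sphere contributes ``C * (-(x - cx) / sqrt(R**2 - (x-cx)**2 -
    (y-cy)**2))`` wherever the radicand is positive, with ``C = (4 pi /
    lambda) * contrast``.  On a sphere boundary the derivative diverges and
    the closed form is undefined.

    Raises
    ------
    BoundaryGradientError
        If any requested point lies exactly on a component boundary
        (radicand == 0).
    """
    xa = np.asarray(x, dtype=float)
    out = np.zeros(np.broadcast(xa, y).shape)
    for comp, contrast in model.components:
        cx, cy, _ = comp.center
        u = xa - cx
        rad = comp.radius**2 - (u**2 + (y - cy) ** 2)
        if np.any(rad == 0.0):
            raise BoundaryGradientError(
                f"lateral gradient undefined on the boundary of the "
                f"component centred at ({cx}, {cy}) (radius {comp.radius})"
            )
        inside = rad > 0.0
        C = 4.0 * np.pi / model.wavelength * contrast
        out = np.where(inside, out + C * (-u / np.sqrt(np.where(inside, rad, 1.0))), out)
    if out.ndim == 0:
        return float(out)
    return out


def add_gaussian_noise(pmap: PhaseMap, noise: NoiseSpec) -> PhaseMap:
    """Add zero-mean white Gaussian noise at the SNR of ``noise``.

    The noise variance is ``P_signal / 10**(snr_db / 10)`` with
    ``P_signal`` the mean squared phase over the full image (zero
    background included).  Reproducible: the seed fixes the realization.

    Raises
    ------
    ZeroSignalError
        If the map is identically zero (signal power undefined).
    """
    power = float(np.mean(pmap.values**2))
    if power == 0.0:
        raise ZeroSignalError("cannot define an SNR for an all-zero phase map")
    sigma = math.sqrt(power / 10.0 ** (noise.snr_db / 10.0))
    rng = np.random.default_rng(noise.seed)
    eps = rng.normal(0.0, sigma, size=pmap.values.shape)
    return PhaseMap(values=pmap.values + eps, grid=pmap.grid)


def nucleated_cell_model(
    *,
    body_radius: float = 6.0,
    nucleus_radius: float = 2.5,
    nucleus_center: tuple[float, float, float] = (3.0, 0.0, 0.0),
    cytoplasm_index: float = 1.37,
    nucleus_index: float = 1.45,
    medium_index: float = 1.33,
    wavelength: float = 0.6328,
) -> CellModel:
    """The reference eccentric-sphere phantom of a nucleated cell.

    Defaults: cytoplasm sphere of radius 6 um at the origin (n = 1.37),
    nucleus of radius 2.5 um centred at (3, 0, 0) (n = 1.45), water-like
    medium (n = 1.33), He-Ne illumination (632.8 nm).
    """
    return CellModel(
        body=SphereComponent((0.0, 0.0, 0.0), body_radius, cytoplasm_index),
        inclusions=(SphereComponent(nucleus_center, nucleus_radius, nucleus_index),),
        medium_index=medium_index,
        wavelength=wavelength,
    )


def nucleated_cell_grid(nx: int = 255, ny: int | None = None) -> GridSpec:
    """The reference 15 x 15 um^2 raster (default 255 x 255 pixels)."""
    return GridSpec(width=15.0, height=15.0, nx=nx, ny=ny if ny is not None else nx)
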
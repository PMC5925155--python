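"""Jump-point detection, nested pairing and morphometric distance reports.

A refractive-index boundary crossed by the traversal shows up in the
forward-difference gradient profile as a localized spike ("jump").  For a
phase hill traversed left to right the jumps come in nested +/- pairs:
the outermost pair is the body outline, inner pairs are inclusions.  Pair
separations in pixels, multiplied by the pixel pitch, give physical sizes.

Detection statistic
-------------------
Boundaries generically fall between pixel centres, so the spike energy is
split across two adjacent forward differences, and noise on a single
difference is amplified by the pixel pitch.  Detection therefore operates
on the pairwise mean ``T[i] = (s[i] + s[i+1]) / 2`` (the two-pixel-span
slope of the phase, centred on difference ``i+1``): suprathreshold samples
of ``|T|`` (relative threshold ``threshold_fraction * max|T|``) are grouped
into contiguous same-sign runs, same-sign runs separated by at most
``merge_gap`` subthreshold samples are merged, and each run reports one
jump at ``argmax |T| + 1`` (ties to the lowest index).  Aggregating two
differences halves the noise variance of both the threshold decision and
the localization, which keeps detected indices stable under phase noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gradients import LineProfile
from .model import GridSpec

__all__ = [
    "JumpPoint",
    "JumpPairSet",
    "DistanceRow",
    "DistanceReport",
    "ErrorStats",
    "PairingError",
    "detect_jumps",
    "pair_jumps",
    "pixel_pair_distance",
    "build_distance_report",
    "diameter_error_stats",
    "error_stats_from_values",
]


class PairingError(ValueError):
    """The jump sequence is not a nested hill pattern (+...+ -...-)."""


@dataclass(frozen=True)
class JumpPoint:
    """A detected boundary spike on a 1D profile.

    ``pixel_index`` is the position along the traversal (in the profile's
    ``pixel_indices`` coordinate), ``sign`` the spike direction in the
    signed gradient (+1 rising, -1 falling), ``magnitude`` the absolute
    signed-gradient value at the spike (rad/um).
    """

    pixel_index: int
    sign: int
    magnitude: float

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise ValueError(f"sign must be +1 or -1, got {self.sign}")
        if not self.magnitude > 0:
            raise ValueError(f"magnitude must be > 0, got {self.magnitude}")


@dataclass(frozen=True)
class JumpPairSet:
    """Nested (left, right) jump pairs, outermost first (label 1, 2, ...)."""

    pairs: tuple[tuple[JumpPoint, JumpPoint], ...]

    def __post_init__(self) -> None:
        prev: tuple[int, int] | None = None
        for left, right in self.pairs:
            if not (left.sign == 1 and right.sign == -1):
                raise PairingError("each pair must be (+ left, - right)")
            if not left.pixel_index < right.pixel_index:
                raise PairingError("pair interval must be nonempty")
            if prev is not None and not (
                prev[0] < left.pixel_index and right.pixel_index < prev[1]
            ):
                raise PairingError("pairs must be strictly nested")
            prev = (left.pixel_index, right.pixel_index)

    def __len__(self) -> int:
        return len(self.pairs)


def detect_jumps(
    profile: LineProfile,
    threshold_fraction: float = 0.5,
    *,
    merge_gap: int = 3,
    signs_from: LineProfile | None = None,
) -> list[JumpPoint]:
    """Detect boundary jumps on a gradient profile.

    Parameters
    ----------
    profile : LineProfile
        Signed gradient samples, or a modulus-squared profile if
        ``signs_from`` supplies the companion signed profile.
    threshold_fraction : float
        Relative threshold in (0, 1): samples of the detection statistic
        with ``|T| >= threshold_fraction * max|T|`` are jump candidates.
    merge_gap : int
        Same-sign suprathreshold runs separated by at most this many
        subthreshold samples are treated as one boundary.
    signs_from : LineProfile, optional
        Signed profile over the same traversal; jump signs and magnitudes
        are read from it (required to pair jumps detected on an
        all-positive squared profile).

    Returns
    -------
    list of JumpPoint, sorted by pixel index.  An all-zero or constant
    profile yields an empty list.
    """
    if not 0 < threshold_fraction < 1:
        raise ValueError(
            f"threshold_fraction must be in (0, 1), got {threshold_fraction}"
        )
    if merge_gap < 0:
        raise ValueError("merge_gap must be >= 0")
    s = np.asarray(profile.samples, dtype=float)
    n = len(s)
    if signs_from is not None and len(signs_from.samples) != n:
        raise ValueError("signs_from must cover the same traversal")
    if profile.squared:
        # restore the gradient-magnitude scale so the relative threshold is
        # commensurate with signed-profile detection; companion signs (if
        # any) restore the spike polarity for run grouping and pairing
        s = np.sqrt(s)
        if signs_from is not None:
            s = np.copysign(s, signs_from.samples)
    if n < 3 or np.ptp(s) == 0.0:
        return []

    T = (s[:-1] + s[1:]) / 2.0  # statistic T[i] straddles difference i+1
    if profile.padded_tail:
        T = T[:-1]  # T[n-2] would localize on the padded terminal index
    if len(T) == 0:
        return []
    peak = float(np.max(np.abs(T)))
    if peak == 0.0:
        return []
    mask = np.abs(T) >= threshold_fraction * peak
    sgn = np.sign(T).astype(int)

    runs: list[list[int]] = []  # [start, stop, sign] over T indices
    i = 0
    nT = len(T)
    while i < nT:
        if mask[i]:
            j = i
            while j + 1 < nT and mask[j + 1] and sgn[j + 1] == sgn[i]:
                j += 1
            runs.append([i, j, sgn[i]])
            i = j + 1
        else:
            i += 1
    merged: list[list[int]] = []
    for run in runs:
        if (
            merged
            and run[2] == merged[-1][2]
            and run[0] - merged[-1][1] - 1 <= merge_gap
        ):
            merged[-1][1] = run[1]
        else:
            merged.append(run)

    signed = signs_from.samples if signs_from is not None else s
    jumps: list[JumpPoint] = []
    for i, j, _ in merged:
        k = i + int(np.argmax(np.abs(T[i : j + 1]))) + 1  # ties -> lowest index
        mag = float(abs(signed[k]))
        sign = int(np.sign(signed[k]))
        if sign == 0 or mag == 0.0:  # degenerate: fall back to the statistic
            sign = int(merged_sign) if (merged_sign := np.sign(T[k - 1])) else 1
            mag = float(abs(T[k - 1]))
        jumps.append(JumpPoint(int(profile.pixel_indices[k]), sign, mag))
    return jumps


def pair_jumps(jumps: list[JumpPoint]) -> JumpPairSet:
    """Pair jumps as nested boundaries: k-th from the left with k-th from
    the right.

    Requires an even count ``2m`` with the first ``m`` signs +1 and the
    last ``m`` signs -1 (a hill with nested inclusions); anything else is
    a :class:`PairingError` (overlapping, non-nested media).
    """
    n = len(jumps)
    signs = [j.sign for j in jumps]
    if n == 0 or n % 2 != 0 or any(
        s != (1 if k < n // 2 else -1) for k, s in enumerate(signs)
    ):
        raise PairingError(
            f"cannot pair jump signature {signs} at indices "
            f"{[j.pixel_index for j in jumps]}: expected m rising then m "
            f"falling jumps"
        )
    m = n // 2
    return JumpPairSet(tuple((jumps[k], jumps[n - 1 - k]) for k in range(m)))


def pixel_pair_distance(i: int, j: int, grid: GridSpec, axis: str = "x") -> float:
    """Physical separation (um) of two pixel indices along an axis:
    exactly ``(j - i) * pitch``."""
    n = grid.nx if axis == "x" else grid.ny
    if not (0 <= i < n and 0 <= j < n):
        raise ValueError(f"indices ({i}, {j}) outside raster of {n} pixels")
    if i > j:
        raise ValueError(f"need i <= j, got ({i}, {j})")
    return (j - i) * grid.pitch(axis)


@dataclass(frozen=True)
class DistanceRow:
    """One labelled separation: a pair diameter or a cross-pair gap."""

    label: str
    kind: str  # "diameter" | "gap_left" | "gap_right"
    left_px: int
    right_px: int
    pixels: int
    microns: float  # exact pixel arithmetic; round only on serialization

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["microns"] = round(self.microns, 3)
        return d


@dataclass(frozen=True)
class DistanceReport:
    """Physical separations for a nested jump-pair set.

    Rows: one diameter per pair (outermost first), then for each adjacent
    nesting level the left-edge gap and right-edge gap, mirroring the
    canonical pair/gap table layout.
    """

    rows: tuple[DistanceRow, ...]
    step_um: float

    @property
    def diameters(self) -> tuple[DistanceRow, ...]:
        return tuple(r for r in self.rows if r.kind == "diameter")

    def to_records(self) -> list[dict]:
        return [r.to_dict() for r in self.rows]


def build_distance_report(
    pairs: JumpPairSet, step_um: float
) -> DistanceReport:
    """Convert a nested pair set into labelled physical separations.

    ``step_um`` is the pixel pitch along the traversal.  Emits pair
    diameters plus left gaps (``left[k+1] - left[k]``) and right gaps
    (``right[k] - right[k+1]``) for each adjacent nesting level.
    """
    if len(pairs) == 0:
        raise ValueError("need at least one pair")
    rows: list[DistanceRow] = []

    def _row(label: str, kind: str, a: int, b: int) -> DistanceRow:
        return DistanceRow(label, kind, a, b, b - a, (b - a) * step_um)

    for k, (left, right) in enumerate(pairs.pairs):
        rows.append(
            _row(f"{k + 1}-{k + 1}", "diameter", left.pixel_index, right.pixel_index)
        )
    for k in range(len(pairs) - 1):
        (l0, r0), (l1, r1) = pairs.pairs[k], pairs.pairs[k + 1]
        rows.append(
            _row(f"{k + 1}-{k + 2} (left)", "gap_left", l0.pixel_index, l1.pixel_index)
        )
        rows.append(
            _row(
                f"{k + 1}-{k + 2} (right)", "gap_right", r1.pixel_index, r0.pixel_index
            )
        )
    return DistanceReport(rows=tuple(rows), step_um=step_um)


@dataclass(frozen=True)
class ErrorStats:
    """Deviation of measured separations from ground-truth set values.

    ``max_diameter_error_um`` is the largest absolute error over the
    diameter rows only; ``mean_relative_error_pct`` averages the relative
    errors over every row with a set value.
    """

    measured_um: tuple[float, ...]
    set_um: tuple[float, ...]
    abs_errors_um: tuple[float, ...]
    rel_errors: tuple[float, ...]
    max_diameter_error_um: float
    mean_relative_error_pct: float

    def to_dict(self) -> dict:
        return {
            "measured_um": list(self.measured_um),
            "set_um": list(self.set_um),
            "abs_errors_um": list(self.abs_errors_um),
            "rel_errors": list(self.rel_errors),
            "max_diameter_error_um": self.max_diameter_error_um,
            "mean_relative_error_pct": self.mean_relative_error_pct,
        }


def error_stats_from_values(
    measured: list[float],
    set_values: list[float],
    diameter_flags: list[bool] | None = None,
) -> ErrorStats:
    """Error statistics from explicit measured/set value lists.

    ``diameter_flags[k]`` marks rows that are pair diameters (default: the
    first half of the rows, matching the report layout for two pairs).
    """
    if len(measured) != len(set_values):
        raise ValueError(
            f"{len(measured)} measured values vs {len(set_values)} set values"
        )
    if any(v == 0 for v in set_values):
        raise ValueError("set values must be nonzero")
    if diameter_flags is None:
        diameter_flags = [k < (len(measured) + 1) // 2 for k in range(len(measured))]
    abs_err = tuple(abs(m - t) for m, t in zip(measured, set_values))
    rel_err = tuple(e / abs(t) for e, t in zip(abs_err, set_values))
    diam_errs = [e for e, d in zip(abs_err, diameter_flags) if d]
    if not diam_errs:
        raise ValueError("at least one diameter row is required")
    return ErrorStats(
        measured_um=tuple(measured),
        set_um=tuple(set_values),
        abs_errors_um=abs_err,
        rel_errors=rel_err,
        max_diameter_error_um=max(diam_errs),
        mean_relative_error_pct=100.0 * sum(rel_err) / len(rel_err),
    )


def diameter_error_stats(report: DistanceReport, truth_um: list[float]) -> ErrorStats:
    """Error statistics of a distance report against ground truth.

    ``truth_um`` holds one set value per report row, in row order.
    """
    if len(truth_um) != len(report.rows):
        raise ValueError(
            f"{len(truth_um)} set values for {len(report.rows)} report rows"
        )
    return error_stats_from_values(
        [r.microns for r in report.rows],
        list(truth_um),
        [r.kind == "diameter" for r in report.rows],
    )
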
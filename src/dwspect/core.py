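"""Core domain types for multi-b-value diffusion decay analysis.

Unit contract used throughout the package: b-values are expressed in
s/mm**2 and diffusion coefficients in mm**2/s, so that the product ``b*D``
entering the forward model ``exp(-b*D)`` is dimensionless.  Unit
conversions happen only inside the acquisition-physics helpers
(:mod:`dwspect.physics`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BValueSchedule",
    "DecayCurve",
    "DGrid",
    "DesignMatrix",
    "RoiMask",
    "normalize_signal",
    "make_d_grid",
    "build_design_matrix",
    "roi_mean_curve",
    "roi_mean_intensities",
    "snr",
]


@dataclass(frozen=True)
class BValueSchedule:
    """Diffusion-weighting schedule: strictly increasing b-values starting at 0.

    The leading b=0 acquisition is mandatory because signal normalization
    divides every intensity by the unweighted one.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("schedule needs at least two b-values")
        if not np.all(np.isfinite(values)):
            raise ValueError("b-values must be finite")
        if values[0] != 0.0:
            raise ValueError("first b-value must be 0 (required for normalization)")
        if np.any(np.diff(values) <= 0):
            raise ValueError("b-values must be strictly increasing")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class DecayCurve:
    """Signal intensities paired with a b-value schedule for one ROI or voxel."""

    schedule: BValueSchedule
    intensities: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        intensities = np.asarray(self.intensities, dtype=float)
        if intensities.shape != (len(self.schedule),):
            raise ValueError(
                f"intensities length {intensities.size} does not match "
                f"schedule length {len(self.schedule)}"
            )
        if not np.all(np.isfinite(intensities)):
            raise ValueError("intensities must be finite")
        if self.normalized and intensities[0] != 1.0:
            raise ValueError("normalized curve must have intensity 1 at b=0")
        object.__setattr__(self, "intensities", intensities)


@dataclass(frozen=True)
class DGrid:
    """Logarithmically spaced grid of candidate diffusion coefficients (mm**2/s)."""

    values: np.ndarray
    d_min: float = 1e-8
    d_max: float = 1e-1

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("grid needs at least two points")
        if values[0] != self.d_min or values[-1] != self.d_max:
            raise ValueError("grid endpoints must equal d_min and d_max")
        if np.any(np.diff(values) <= 0):
            raise ValueError("grid must be strictly increasing")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class DesignMatrix:
    """Forward operator ``entries[i, j] = exp(-b_i * D_j)`` mapping a weight
    spectrum on the D-grid to normalized signal intensities."""

    entries: np.ndarray
    schedule: BValueSchedule
    grid: DGrid

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=float)
        if entries.shape != (len(self.schedule), len(self.grid)):
            raise ValueError("design matrix shape must be n_b x n_D")
        object.__setattr__(self, "entries", entries)

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape


@dataclass(frozen=True)
class RoiMask:
    """Boolean voxel mask congruent with the spatial axes of an image stack."""

    data: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=bool)
        object.__setattr__(self, "data", data)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def normalize_signal(curve: DecayCurve) -> DecayCurve:
    """Divide every intensity by the b=0 intensity.

    Raises
    ------
    ValueError
        If the curve is already normalized (re-normalizing would silently
        rescale) or the b=0 intensity is not strictly positive.
    """
    if curve.normalized:
        raise ValueError("curve is already normalized")
    i0 = curve.intensities[0]
    if i0 <= 0:
        raise ValueError(f"b=0 intensity must be strictly positive, got {i0}")
    out = curve.intensities / i0
    out[0] = 1.0  # exact, regardless of rounding
    return DecayCurve(curve.schedule, out, normalized=True)


def make_d_grid(n_points: int = 200, d_min: float = 1e-8, d_max: float = 1e-1) -> DGrid:
    """Build a log-uniform diffusion-coefficient grid.

    Consecutive values share the constant ratio ``(d_max/d_min)**(1/(n-1))``;
    both endpoints are included exactly.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if not (0 < d_min < d_max):
        raise ValueError("require 0 < d_min < d_max")
    values = np.geomspace(d_min, d_max, n_points)
    values[0], values[-1] = d_min, d_max
    return DGrid(values, d_min=d_min, d_max=d_max)


def build_design_matrix(schedule: BValueSchedule, grid: DGrid) -> DesignMatrix:
    """Forward model ``A[i, j] = exp(-b_i * D_j)`` (b in s/mm**2, D in mm**2/s).

    Entries for very large ``b*D`` underflow gracefully to 0.
    """
    with np.errstate(under="ignore"):
        entries = np.exp(-np.outer(schedule.values, grid.values))
    return DesignMatrix(entries, schedule, grid)


def roi_mean_intensities(image_stack: np.ndarray, roi: RoiMask) -> np.ndarray:
    """Per-b-value mean intensity over the masked voxels."""
    stack = np.asarray(image_stack, dtype=float)
    if roi.data.shape != stack.shape[:-1]:
        raise ValueError(
            f"mask shape {roi.data.shape} does not match image planes {stack.shape[:-1]}"
        )
    if roi.n_voxels == 0:
        raise ValueError(f"mask {roi.label!r} selects no voxels")
    return stack[roi.data].mean(axis=0)


def snr(image_stack: np.ndarray, roi: RoiMask, noise_sigma: float) -> np.ndarray:
    """Per-b-value signal-to-noise ratio: masked mean divided by a supplied
    noise standard deviation (e.g. from a background ROI or known simulation
    ground truth)."""
    if noise_sigma <= 0:
        raise ValueError("noise_sigma must be positive")
    return roi_mean_intensities(image_stack, roi) / noise_sigma


def roi_mean_curve(
    image_stack: np.ndarray, roi: RoiMask, schedule: BValueSchedule
) -> DecayCurve:
    """Average the decay signal over a mask into a raw :class:`DecayCurve`.

    ``image_stack`` has shape ``(*spatial, n_b)``; the mask must match the
    spatial axes and the b-axis length must match the schedule.
    """
    means = roi_mean_intensities(image_stack, roi)
    if means.size != len(schedule):
        raise ValueError("stack b-axis length does not match schedule")
    return DecayCurve(schedule, means)
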
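"""Multiscale local-polynomial smoothing of decay curves.

Voxel-level decay curves at ultra-high b-values are noisy; smoothing the
curve along the b-axis before spectrum inversion stabilizes voxel-wise
fits.  The default smoother averages windowed cubic (Savitzky-Golay) fits
at two dyadic window sizes, applied to the log-intensity — a mixture of
exponentials is far closer to locally polynomial in log-signal than in
signal, and exponentiating back guarantees a positive smoothed curve, as
magnitude MRI data are.  The smoothed curve is rescaled so the b=0 point
is preserved exactly.  The smoother is pluggable: any callable mapping an
intensity vector to a same-length vector can be swapped in.

Fidelity is measured on the normalized-signal scale (absolute deviation):
relative error is meaningless in the deep tail where the decay underflows.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy.signal import savgol_filter

from .core import DecayCurve

__all__ = ["denoise_curve", "multiscale_local_poly"]

#: Dyadic window sizes (in samples) of the default smoother.
DEFAULT_SCALES: tuple[int, ...] = (5, 9)
#: Local polynomial order; cubic tracks the curvature of log-decay curves.
DEFAULT_POLYORDER = 3


def multiscale_local_poly(
    values: np.ndarray,
    scales: Sequence[int] = DEFAULT_SCALES,
    polyorder: int = DEFAULT_POLYORDER,
) -> np.ndarray:
    """Average of local-polynomial fits of log-intensity at several scales.

    Each scale is a Savitzky-Golay pass on ``log(values)``; windows are
    clipped to the signal length and forced odd.  Non-positive samples
    (possible under additive noise) are clipped to a tiny positive floor
    before taking logs.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    floor = max(values.max(), 0.0) * 1e-12
    if floor <= 0:
        raise ValueError("curve has no positive samples")
    log_values = np.log(np.maximum(values, floor))
    out = np.zeros_like(log_values)
    used = 0
    for scale in scales:
        window = min(int(scale), n if n % 2 == 1 else n - 1)
        if window % 2 == 0:
            window -= 1
        if window <= polyorder:
            continue
        out += savgol_filter(log_values, window, polyorder)
        used += 1
    if used == 0:
        raise ValueError("no usable smoothing scale for this curve length")
    return np.exp(out / used)


def denoise_curve(
    curve: DecayCurve,
    scales: Sequence[int] = DEFAULT_SCALES,
    smoother: Callable[[np.ndarray], np.ndarray] | None = None,
) -> DecayCurve:
    """Smooth a decay curve along the b-axis, preserving the b=0 intensity.

    The b=0 sample is reset to the input's value after smoothing (for a
    normalized curve this keeps it normalized); the interior points keep
    their smoothed values, avoiding amplification of the boundary-fit
    error into the rest of the curve.  Requires at least 5 points.
    """
    if len(curve.schedule) < 5:
        raise ValueError("denoising needs at least 5 points")
    y = curve.intensities
    smoothed = smoother(y) if smoother is not None else multiscale_local_poly(y, scales)
    smoothed = np.asarray(smoothed, dtype=float).copy()
    if smoothed.shape != y.shape:
        raise ValueError("smoother changed the curve length")
    smoothed[0] = y[0]
    return DecayCurve(curve.schedule, smoothed, normalized=curve.normalized)
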
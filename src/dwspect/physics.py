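"""Acquisition-physics helpers: pulsed-gradient b-value and Einstein length scale.

These are the only places in the package where units other than the
b [s/mm**2] / D [mm**2/s] contract appear; conversions are internal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_PROTON = 2.675e8

_GAUSS_PER_CM_TO_T_PER_M = 1e-2  # 1 G/cm = 1e-4 T / 1e-2 m
_PER_M2_TO_S_PER_MM2 = 1e-6

__all__ = ["AcquisitionParams", "GAMMA_PROTON", "stejskal_tanner_b", "einstein_displacement"]


@dataclass(frozen=True)
class AcquisitionParams:
    """Pulsed-gradient diffusion-encoding parameters.

    Parameters
    ----------
    gradient_strength
        Diffusion gradient amplitude G, in Gauss/cm (the unit MRI consoles
        report; converted to T/m internally).
    delta
        Gradient pulse duration delta, in seconds.
    Delta
        Diffusion time (pulse separation) Delta, in seconds; must exceed
        ``delta``.
    gamma
        Gyromagnetic ratio, rad s^-1 T^-1; defaults to the proton value.
    """

    gradient_strength: float
    delta: float
    Delta: float
    gamma: float = GAMMA_PROTON

    def __post_init__(self) -> None:
        if self.gradient_strength < 0:
            raise ValueError("gradient_strength must be non-negative")
        if self.delta <= 0 or self.Delta <= 0 or self.gamma <= 0:
            raise ValueError("delta, Delta and gamma must be positive")
        if self.delta >= self.Delta:
            raise ValueError("gradient duration delta must be shorter than Delta")


def stejskal_tanner_b(params: AcquisitionParams) -> float:
    """Diffusion-weighting factor b = gamma^2 G^2 delta^2 (Delta - delta/3),
    returned in s/mm**2.

    With G = 50 Gauss/cm, delta = 11 ms, Delta = 400 ms and the proton
    gamma this evaluates to ~8.58e5 s/mm**2, the top of the ultra-high
    b-value range this package targets.
    """
    g_si = params.gradient_strength * _GAUSS_PER_CM_TO_T_PER_M
    b_si = (params.gamma * g_si * params.delta) ** 2 * (params.Delta - params.delta / 3.0)
    return b_si * _PER_M2_TO_S_PER_MM2


def einstein_displacement(D: float, Delta: float) -> float:
    """Root-mean-square 1-D displacement sqrt(2*D*Delta) in micrometres.

    ``D`` is in mm**2/s and ``Delta`` (the diffusion time) in seconds; the
    result converts mm to um.  This is the characteristic length scale a
    diffusion measurement at diffusion time ``Delta`` probes for water
    decaying at rate ``D``.
    """
    if D < 0:
        raise ValueError("D must be non-negative")
    if Delta <= 0:
        raise ValueError("Delta must be positive")
    return float(np.sqrt(2.0 * D * Delta) * 1e3)
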
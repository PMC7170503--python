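"""Synthetic multi-compartment decay curves, phantoms, and two-group studies.

The forward model is a discrete mixture of mono-exponential decays,
``s(b) = amplitude * sum_j f_j * exp(-b * D_j)`` with fractions summing to
one, observed under Rician (magnitude-MRI) or Gaussian noise.  Defaults
emulate the conditions of an ex vivo mouse spinal-cord study: a 30-point
b-value schedule spanning 0 to 8.58e5 s/mm**2, groups of 7 (mutant-like)
and 8 (control-like) subjects, a four-compartment lumbar-cord-like base
mixture, 10% between-subject log-normal jitter on fractions, and Rician
noise at a b=0 SNR of 30.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BValueSchedule, DecayCurve, DGrid, RoiMask

__all__ = [
    "CompartmentSpec",
    "PhantomSpec",
    "GroupStudySpec",
    "default_schedule",
    "default_mixture",
    "mixture_signal",
    "simulate_decay",
    "simulate_phantom",
    "simulate_group_study",
    "perturb_mixture",
    "truth_sums",
]

#: Maximum b-value (s/mm**2) of the default schedule — the top of the
#: ultra-high-b-value range reachable at 50 Gauss/cm with an 11 ms pulse
#: and 400 ms diffusion time.
B_MAX_DEFAULT = 858_022.0


def default_schedule(
    n_b: int = 30, b_first: float = 1e2, b_max: float = B_MAX_DEFAULT
) -> BValueSchedule:
    """30-point schedule: b=0 plus log-spaced values from ``b_first`` to
    ``b_max``.  Only the count and the range of the emulated acquisition
    are known, so the interior spacing is a package choice; downstream
    analyses must not depend on the exact spacing."""
    values = np.concatenate([[0.0], np.geomspace(b_first, b_max, n_b - 1)])
    return BValueSchedule(values)


@dataclass(frozen=True)
class CompartmentSpec:
    """One diffusion compartment: coefficient D (mm**2/s) and signal fraction."""

    D: float
    fraction: float

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError("compartment D must be positive")
        if self.fraction < 0:
            raise ValueError("compartment fraction must be non-negative")


def default_mixture() -> tuple[CompartmentSpec, ...]:
    """Four-compartment control-like spinal-cord mixture.

    Compartment diffusivities sit at the four main spectral peaks observed
    in control cord (1.1e-6, 1.47e-5, 1.2e-4 and 6.08e-4 mm**2/s); the
    fractions apportion the signal roughly as the control group's
    subinterval weight sums do (slow compartments carrying ~12% and ~24%,
    the two faster ones the remainder).
    """
    return (
        CompartmentSpec(D=1.10e-6, fraction=0.12),
        CompartmentSpec(D=1.47e-5, fraction=0.24),
        CompartmentSpec(D=1.20e-4, fraction=0.35),
        CompartmentSpec(D=6.08e-4, fraction=0.29),
    )


def _check_mixture(mixture) -> tuple[np.ndarray, np.ndarray]:
    ds = np.array([c.D for c in mixture], dtype=float)
    fs = np.array([c.fraction for c in mixture], dtype=float)
    if fs.size == 0:
        raise ValueError("mixture is empty")
    if abs(fs.sum() - 1.0) > 1e-9:
        raise ValueError(f"mixture fractions must sum to 1, got {fs.sum():.6g}")
    return ds, fs


def mixture_signal(mixture, schedule: BValueSchedule) -> np.ndarray:
    """Noise-free normalized signal sum_j f_j exp(-b D_j) at each b-value."""
    ds, fs = _check_mixture(mixture)
    with np.errstate(under="ignore"):
        return np.exp(-np.outer(schedule.values, ds)) @ fs


def _add_noise(
    signal: np.ndarray, sigma: float, noise_model: str, rng: np.random.Generator
) -> np.ndarray:
    if sigma == 0:
        return signal.copy()
    if noise_model == "rician":
        n1 = rng.normal(0.0, sigma, signal.shape)
        n2 = rng.normal(0.0, sigma, signal.shape)
        return np.sqrt((signal + n1) ** 2 + n2**2)
    if noise_model == "gaussian":
        return signal + rng.normal(0.0, sigma, signal.shape)
    raise ValueError(f"unknown noise model {noise_model!r}")


def simulate_decay(
    mixture,
    schedule: BValueSchedule | None = None,
    snr: float = 30.0,
    noise_model: str = "rician",
    seed: int | np.random.Generator = 0,
) -> DecayCurve:
    """One raw (un-normalized) noisy decay curve for a compartment mixture.

    The noise standard deviation is fixed at sigma=1 and the noise-free
    b=0 amplitude is scaled to ``snr``, so ``snr`` is the b=0 SNR.
    ``snr=np.inf`` gives the noise-free forward signal.  Rician noise is
    the magnitude-MRI model sqrt((s+n1)**2 + n2**2); Gaussian is offered
    for oracle tests with closed-form means.
    """
    schedule = schedule or default_schedule()
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    clean = mixture_signal(mixture, schedule)
    if np.isinf(snr):
        return DecayCurve(schedule, clean)
    amplitude = float(snr)  # sigma = 1
    noisy = _add_noise(amplitude * clean, 1.0, noise_model, rng)
    return DecayCurve(schedule, noisy)


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative description of a 4-D digital phantom.

    ``regions`` maps a label to ``(mask, mixture)``; region masks must be
    pairwise disjoint.  Voxels outside every region stay at 0 signal.
    """

    shape: tuple[int, int, int]
    regions: dict
    schedule: BValueSchedule = field(default_factory=default_schedule)
    snr: float = 30.0
    noise_model: str = "rician"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        total = np.zeros(self.shape, dtype=int)
        for label, (mask, mixture) in self.regions.items():
            m = np.asarray(mask, dtype=bool)
            if m.shape != self.shape:
                raise ValueError(f"region {label!r} mask shape mismatch")
            total += m
            _check_mixture(mixture)
        if np.any(total > 1):
            raise ValueError("phantom regions overlap")


def simulate_phantom(spec: PhantomSpec, grid: DGrid | None = None):
    """Simulate a 4-D stack from a phantom spec.

    Returns ``(stack, truth_weights, masks)`` where ``stack`` has shape
    ``(*spec.shape, n_b)``, ``truth_weights`` (present when a ``grid`` is
    given) has shape ``(*spec.shape, n_D)`` holding each voxel's generating
    fractions placed at the nearest grid point, and ``masks`` maps region
    labels to :class:`RoiMask`.
    """
    rng = np.random.default_rng(spec.seed)
    noise_free = np.isinf(spec.snr)
    n_b = len(spec.schedule)
    stack = np.zeros(spec.shape + (n_b,), dtype=float)
    truth = np.zeros(spec.shape + (len(grid),), dtype=float) if grid is not None else None
    masks = {}
    for label, (mask, mixture) in spec.regions.items():
        m = np.asarray(mask, dtype=bool)
        masks[label] = RoiMask(m, label=label)
        base = mixture_signal(mixture, spec.schedule)
        clean = base if noise_free else spec.snr * base
        idx = np.argwhere(m)
        for vox in idx:
            stack[tuple(vox)] = (
                clean if noise_free else _add_noise(clean, 1.0, spec.noise_model, rng)
            )
        if grid is not None:
            w = np.zeros(len(grid))
            for comp in mixture:
                j = int(np.argmin(np.abs(np.log10(grid.values) - np.log10(comp.D))))
                w[j] += comp.fraction
            truth[m] = w
    return stack, truth, masks


def perturb_mixture(mixture, band_deltas: dict) -> tuple[CompartmentSpec, ...]:
    """Shift the total fraction of targeted D-bands by stated amounts.

    ``band_deltas`` maps ``(d_low, d_high)`` bands to additive fraction
    changes.  Compartments inside a band share its delta proportionally to
    their fractions; untargeted compartments are rescaled by a common
    factor so the fractions again sum to one.  A perturbation driving any
    fraction negative raises.
    """
    ds, fs = _check_mixture(mixture)
    new = fs.copy()
    targeted = np.zeros(fs.size, dtype=bool)
    for (lo, hi), delta in band_deltas.items():
        in_band = (ds >= lo) & (ds <= hi)
        if not in_band.any():
            raise ValueError(f"no compartment lies in band [{lo:g}, {hi:g}]")
        band_total = fs[in_band].sum()
        if band_total + delta < 0:
            raise ValueError("perturbation drives a band fraction negative")
        new[in_band] = fs[in_band] * (band_total + delta) / band_total
        targeted |= in_band
    rest = ~targeted
    rest_total = new[rest].sum()
    needed = 1.0 - new[targeted].sum()
    if needed < 0 or (rest_total == 0 and needed > 0):
        raise ValueError("perturbations cannot be renormalized")
    if rest.any() and rest_total > 0:
        new[rest] *= needed / rest_total
    if np.any(new < 0):
        raise ValueError("perturbation drives a fraction negative")
    return tuple(CompartmentSpec(D=d, fraction=f) for d, f in zip(ds, new))


def _jitter_fractions(
    fractions: np.ndarray, scale: float, rng: np.random.Generator
) -> np.ndarray:
    if scale == 0:
        return fractions.copy()
    jittered = fractions * np.exp(rng.normal(0.0, scale, fractions.shape))
    return jittered / jittered.sum()


@dataclass(frozen=True)
class GroupStudySpec:
    """Two-group study design with compartment-fraction group effects.

    Group B is control-like (the base mixture); group A is mutant-like,
    its mixture perturbed by ``band_deltas`` (see :func:`perturb_mixture`).
    Each subject draws multiplicative log-normal jitter of scale
    ``subject_jitter`` on its fractions (renormalized) before the noisy
    decay curve is simulated.
    """

    n_a: int = 7
    n_b: int = 8
    base_mixture: tuple = field(default_factory=default_mixture)
    band_deltas: dict = field(default_factory=dict)
    subject_jitter: float = 0.10
    schedule: BValueSchedule = field(default_factory=default_schedule)
    snr: float = 30.0
    noise_model: str = "rician"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_a < 1 or self.n_b < 1:
            raise ValueError("each group needs at least one subject")
        _check_mixture(self.base_mixture)


def simulate_group_study(spec: GroupStudySpec):
    """Simulate per-subject decay curves for a two-group study.

    Returns ``(curves_a, curves_b, truth)`` where each curves list holds
    raw noisy :class:`DecayCurve` objects and ``truth`` is a dict with the
    generating mixtures and each subject's jittered fractions.
    """
    rng = np.random.default_rng(spec.seed)
    mixture_b = tuple(spec.base_mixture)
    mixture_a = perturb_mixture(mixture_b, spec.band_deltas) if spec.band_deltas else mixture_b
    ds = np.array([c.D for c in mixture_b])

    def _subjects(mixture, n):
        fs = np.array([c.fraction for c in mixture])
        curves, subject_fracs = [], []
        for _ in range(n):
            f = _jitter_fractions(fs, spec.subject_jitter, rng)
            mix = tuple(CompartmentSpec(D=d, fraction=fr) for d, fr in zip(ds, f))
            curves.append(
                simulate_decay(mix, spec.schedule, spec.snr, spec.noise_model, rng)
            )
            subject_fracs.append(f)
        return curves, np.array(subject_fracs)

    curves_a, fracs_a = _subjects(mixture_a, spec.n_a)
    curves_b, fracs_b = _subjects(mixture_b, spec.n_b)
    truth = {
        "mixture_a": mixture_a,
        "mixture_b": mixture_b,
        "fractions_a": fracs_a,
        "fractions_b": fracs_b,
        "compartment_D": ds,
    }
    return curves_a, curves_b, truth


def truth_sums(mixture, partition) -> np.ndarray:
    """Ground-truth per-subinterval fraction sums for a mixture, using the
    same half-open membership convention as the spectrum analysis."""
    ds, fs = _check_mixture(mixture)
    out = np.zeros(partition.n_subintervals)
    for k in range(partition.n_subintervals):
        lo, hi = partition.bounds(k)
        if k == partition.n_subintervals - 1:
            sel = (ds >= lo) & (ds <= hi)
        else:
            sel = (ds >= lo) & (ds < hi)
        out[k] = fs[sel].sum()
    return out
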
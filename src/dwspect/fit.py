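"""Regularized non-negative least-squares inversion of diffusion decay curves.

The normalized decay signal is modelled as a non-negative mixture of
exponentials over a fixed logarithmic grid of diffusion coefficients:

    I_n = A @ W,   A[i, j] = exp(-b_i * D_j),   W >= 0.

Plain NNLS is ill-conditioned for this inverse problem, so an energy
(Tikhonov) penalty ``mu * W.T @ W`` is added and its weight ``mu`` is tuned
so that the regularized chi-square misfit exceeds the unregularized one by
a fixed relative amount ``alpha`` (default 9%):

    chi2_reg(mu) = (1 + alpha) * chi2_nonreg.

Because chi2_reg is monotone non-decreasing in mu, the target is located by
geometric bracket expansion followed by bisection on log(mu).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .core import DGrid, DecayCurve, DesignMatrix, build_design_matrix, normalize_signal
from .denoise import denoise_curve

__all__ = [
    "Spectrum",
    "FitConfig",
    "ConvergenceError",
    "nnls",
    "chi_square",
    "rnnls_solve",
    "select_mu",
    "fit_spectrum",
]


class ConvergenceError(RuntimeError):
    """The iterative regularization-weight search failed to converge."""


@dataclass(frozen=True)
class Spectrum:
    """One fitted diffusion-weight spectrum.

    Attributes
    ----------
    grid
        The diffusion-coefficient grid the weights live on.
    weights
        Non-negative weights W, one per grid point; fractions of the
        normalized b=0 signal (not renormalized to sum to 1).
    mu
        Regularization weight used for the fit (0 means unregularized).
    chi2_ratio
        Achieved chi2_reg / chi2_nonreg (1.0 for an unregularized fit).
    """

    grid: DGrid
    weights: np.ndarray
    mu: float = 0.0
    chi2_ratio: float = 1.0

    def __post_init__(self) -> None:
        weights = np.asarray(self.weights, dtype=float)
        if weights.shape != (len(self.grid),):
            raise ValueError("weights length must match grid length")
        if not np.all(np.isfinite(weights)):
            raise ValueError("weights must be finite")
        if np.any(weights < 0):
            raise ValueError("weights must be non-negative")
        object.__setattr__(self, "weights", weights)

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the chi-square-targeted regularization search.

    Attributes
    ----------
    alpha
        Relative chi-square inflation target; the accepted fit satisfies
        chi2_reg = chi2_nonreg * (1 + alpha).  Default 0.09.
    mu_tolerance
        Absolute tolerance on the achieved chi2 ratio (equivalently on the
        achieved inflation), default 1e-3.
    mu_bracket
        Initial (low, high) bounds for the geometric bracket search on mu.
    max_iterations
        Cap on bracket-expansion and bisection steps.
    sigma2
        Noise variance entering the chi-square.  ``None`` selects the
        self-contained default: the mean squared residual of the
        unregularized fit.  Note the mu search depends only on the *ratio*
        of misfits, which is independent of sigma2.
    """

    alpha: float = 0.09
    mu_tolerance: float = 1e-3
    mu_bracket: tuple[float, float] = (1e-8, 1.0)
    max_iterations: int = 100
    sigma2: float | None = None

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.mu_tolerance <= 0:
            raise ValueError("mu_tolerance must be positive")
        lo, hi = self.mu_bracket
        if not (0 < lo < hi):
            raise ValueError("mu_bracket must satisfy 0 < low < high")
        if self.sigma2 is not None and self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive when supplied")


def _as_matrix(design: DesignMatrix | np.ndarray) -> np.ndarray:
    return design.entries if isinstance(design, DesignMatrix) else np.asarray(design, float)


def nnls(design: DesignMatrix | np.ndarray, y: np.ndarray) -> np.ndarray:
    """Non-negative least squares: argmin_{W>=0} ||A W - y||^2.

    Thin wrapper over the Lawson-Hanson active-set solver
    (:func:`scipy.optimize.nnls`), with input validation.
    """
    A = _as_matrix(design)
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or A.shape[0] != y.size:
        raise ValueError(f"design rows {A.shape[0]} must match y length {y.size}")
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in design or data")
    w, _ = scipy.optimize.nnls(A, y)
    return w


def chi_square(y: np.ndarray, y_hat: np.ndarray, sigma2: float) -> float:
    """Chi-square misfit sum((y - y_hat)**2) / sigma2."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have equal length")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    r = y - y_hat
    return float(r @ r / sigma2)


def rnnls_solve(
    design: DesignMatrix | np.ndarray, y: np.ndarray, mu: float
) -> np.ndarray:
    """Energy-regularized NNLS: argmin_{W>=0} ||A W - y||^2 + mu * W.T W.

    Solved exactly as plain NNLS on the augmented system

        [[A], [sqrt(mu) * I]] @ W  ~  [y, 0],

    whose least-squares objective expands to the regularized one, so the
    equivalence is algebraic rather than approximate.
    """
    if mu < 0:
        raise ValueError("mu must be non-negative")
    A = _as_matrix(design)
    y = np.asarray(y, dtype=float)
    if mu == 0:
        return nnls(A, y)
    n_d = A.shape[1]
    A_aug = np.vstack([A, np.sqrt(mu) * np.eye(n_d)])
    y_aug = np.concatenate([y, np.zeros(n_d)])
    return nnls(A_aug, y_aug)


def select_mu(
    design: DesignMatrix | np.ndarray, y: np.ndarray, config: FitConfig | None = None
) -> Spectrum:
    """Pick the regularization weight hitting the chi-square inflation target.

    Iteratively updates mu until chi2_reg / chi2_nonreg = 1 + alpha within
    ``config.mu_tolerance``: the bracket ``config.mu_bracket`` is expanded
    geometrically until it straddles the target, then bisection on log(mu)
    closes in.  Returns the :class:`Spectrum` at the accepted mu.

    Raises
    ------
    ValueError
        If the unregularized misfit is zero (noise-free data; use mu=0
        directly, there is nothing to regularize against).
    ConvergenceError
        If no bracket containing the target can be established, or
        bisection exhausts ``max_iterations``; the message reports the last
        bracket examined.
    """
    config = config or FitConfig()
    A = _as_matrix(design)
    y = np.asarray(y, dtype=float)
    grid = design.grid if isinstance(design, DesignMatrix) else None

    w0 = nnls(A, y)
    resid0 = y - A @ w0
    sigma2 = config.sigma2 if config.sigma2 is not None else float(np.mean(resid0**2))
    # a relative residual below 0.1% means the data are effectively
    # noise-free (only grid-resolution misfit remains): there is no noise
    # misfit to inflate by (1 + alpha)
    degenerate = np.linalg.norm(resid0) <= 1e-3 * max(np.linalg.norm(y), 1e-300)
    if sigma2 == 0 or degenerate:
        raise ValueError(
            "unregularized fit is exact (chi2_nonreg = 0); data are noise-free "
            "— use mu=0 (rnnls_solve with mu=0) instead of chi2-targeted selection"
        )
    chi2_nonreg = chi_square(y, A @ w0, sigma2)
    target = 1.0 + config.alpha

    def _make(w: np.ndarray, mu: float, ratio: float) -> Spectrum:
        g = grid if grid is not None else DGrid(
            np.geomspace(1e-8, 1e-1, A.shape[1]), 1e-8, 1e-1
        )
        return Spectrum(g, w, mu=mu, chi2_ratio=ratio)

    if config.alpha == 0:
        return _make(w0, 0.0, 1.0)

    def ratio_at(mu: float) -> tuple[float, np.ndarray]:
        w = rnnls_solve(A, y, mu)
        return chi_square(y, A @ w, sigma2) / chi2_nonreg, w

    tol = config.mu_tolerance
    lo, hi = config.mu_bracket
    r_lo, w_lo = ratio_at(lo)
    if abs(r_lo - target) <= tol:
        return _make(w_lo, lo, r_lo)
    r_hi, w_hi = ratio_at(hi)
    if abs(r_hi - target) <= tol:
        return _make(w_hi, hi, r_hi)

    # expand the bracket geometrically until it straddles the target ratio
    it = 0
    while r_lo > target:
        lo /= 10.0
        r_lo, w_lo = ratio_at(lo)
        if abs(r_lo - target) <= tol:
            return _make(w_lo, lo, r_lo)
        it += 1
        if it > config.max_iterations:
            raise ConvergenceError(
                f"could not bracket chi2 target from below; last mu={lo:g} "
                f"ratio={r_lo:g}"
            )
    while r_hi < target:
        hi *= 10.0
        r_hi, w_hi = ratio_at(hi)
        if abs(r_hi - target) <= tol:
            return _make(w_hi, hi, r_hi)
        it += 1
        if it > config.max_iterations:
            raise ConvergenceError(
                f"could not bracket chi2 target from above; last mu={hi:g} "
                f"ratio={r_hi:g}"
            )

    # bisection on log(mu); chi2_reg(mu) is monotone non-decreasing
    for _ in range(config.max_iterations):
        mid = float(np.sqrt(lo * hi))
        r_mid, w_mid = ratio_at(mid)
        if abs(r_mid - target) <= tol:
            return _make(w_mid, mid, r_mid)
        if r_mid < target:
            lo = mid
        else:
            hi = mid
    raise ConvergenceError(
        f"mu bisection did not reach |ratio-(1+alpha)| <= {tol:g} within "
        f"{config.max_iterations} iterations; last bracket [{lo:g}, {hi:g}]"
    )


def fit_spectrum(
    curve: DecayCurve,
    grid: DGrid,
    config: FitConfig | None = None,
    denoise: bool = False,
) -> Spectrum:
    """End-to-end spectrum fit for one decay curve.

    Normalizes the curve if it is raw, optionally denoises it, builds the
    exp(-b*D) design matrix, and runs the chi2-targeted regularization
    search.  With ``config.alpha == 0`` the fit degenerates to plain NNLS.
    """
    config = config or FitConfig()
    if not curve.normalized:
        curve = normalize_signal(curve)
    if np.all(curve.intensities[1:] == 0):
        raise ValueError("all diffusion-weighted intensities are zero")
    if denoise:
        curve = denoise_curve(curve)
    design = build_design_matrix(curve.schedule, grid)
    if config.alpha == 0:
        w = nnls(design, curve.intensities)
        return Spectrum(grid, w, mu=0.0, chi2_ratio=1.0)
    return select_mu(design, curve.intensities, config)
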
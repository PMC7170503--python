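"""Group-level spectrum comparison via crossover-defined subintervals.

The per-subject diffusion-weight spectra of two groups are averaged
pointwise; grid locations where the ordering of the two mean spectra
inverts ("crossover points") partition the D-axis into subintervals.
Within each subinterval the sum of averaged weights (S_aDw, one value per
group), its between-group difference (dS_aDw), and per-subject sums of
weights (S_Dw) are computed; S_Dw is compared between groups with a
two-sample Student t test per subinterval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .core import DGrid
from .fit import Spectrum

__all__ = [
    "GroupSpectra",
    "SubintervalPartition",
    "WeightSummary",
    "TestResult",
    "average_spectra",
    "find_crossovers",
    "sum_weights",
    "subinterval_sums",
    "delta_sadw",
    "rank_abs_differences",
    "ttest_sdw",
    "spectrum_peaks",
]


@dataclass(frozen=True)
class GroupSpectra:
    """A labelled collection of spectra sharing one D-grid, with their
    pointwise mean weights <W>."""

    label: str
    spectra: tuple[Spectrum, ...]
    mean_weights: np.ndarray

    @property
    def grid(self) -> DGrid:
        return self.spectra[0].grid

    @property
    def n_subjects(self) -> int:
        return len(self.spectra)


@dataclass(frozen=True)
class SubintervalPartition:
    """D-axis partition: boundaries from d_min to d_max, interior boundaries
    at crossover grid points.

    Grid-point membership is half-open [lower, upper); the final
    subinterval is closed so every grid point belongs to exactly one
    subinterval.
    """

    boundaries: np.ndarray
    grid: DGrid

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.size < 2 or np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be strictly increasing, length >= 2")
        if b[0] != self.grid.d_min or b[-1] != self.grid.d_max:
            raise ValueError("outer boundaries must be the grid endpoints")
        gv = self.grid.values
        for i, interior in enumerate(b[1:-1], start=1):
            j = int(np.argmin(np.abs(gv - interior)))
            if abs(gv[j] - interior) > 1e-6 * interior:
                raise ValueError(f"interior boundary {interior:g} is not a grid point")
            b[i] = gv[j]  # snap away float round-trip noise
        object.__setattr__(self, "boundaries", b)

    @property
    def n_subintervals(self) -> int:
        return self.boundaries.size - 1

    def bounds(self, k: int) -> tuple[float, float]:
        if not 0 <= k < self.n_subintervals:
            raise IndexError(f"subinterval index {k} out of range")
        return float(self.boundaries[k]), float(self.boundaries[k + 1])

    def membership(self, k: int) -> np.ndarray:
        """Boolean mask of grid points in subinterval k ([lower, upper),
        last subinterval closed)."""
        lo, hi = self.bounds(k)
        gv = self.grid.values
        if k == self.n_subintervals - 1:
            return (gv >= lo) & (gv <= hi)
        return (gv >= lo) & (gv < hi)


@dataclass(frozen=True)
class TestResult:
    """Two-sample t test of per-subject S_Dw in one subinterval."""

    subinterval: int
    t: float
    p: float
    n_a: int
    n_b: int

    @property
    def significant(self) -> bool:
        return self.p < 0.05


@dataclass(frozen=True)
class WeightSummary:
    """Per-subinterval weight statistics for a two-group comparison."""

    partition: SubintervalPartition
    sadw_a: np.ndarray  # per-subinterval sum of group-A mean weights
    sadw_b: np.ndarray
    sdw_a: np.ndarray  # (n_subjects_a, n_subintervals) per-subject sums
    sdw_b: np.ndarray
    delta: np.ndarray  # sadw_a - sadw_b

    @property
    def n_subintervals(self) -> int:
        return self.partition.n_subintervals


def average_spectra(spectra, label: str = "") -> GroupSpectra:
    """Pointwise arithmetic mean of a group's spectra (Eq. for <W>)."""
    spectra = tuple(spectra)
    if not spectra:
        raise ValueError("need at least one spectrum")
    grid = spectra[0].grid
    for s in spectra[1:]:
        if len(s.grid) != len(grid) or not np.array_equal(s.grid.values, grid.values):
            raise ValueError("all spectra must share one D-grid")
    mean = np.mean([s.weights for s in spectra], axis=0)
    return GroupSpectra(label=label, spectra=spectra, mean_weights=mean)


def find_crossovers(group_a: GroupSpectra, group_b: GroupSpectra) -> SubintervalPartition:
    """Partition the D-axis at grid points where the group mean spectra invert.

    A crossover is a strict sign change of ``mean_a - mean_b`` between
    consecutive grid points with nonzero difference on both sides; the
    boundary is placed at the first grid point carrying the new sign.  Runs
    of exact zeros are collapsed: a sign change across a zero-run yields a
    single boundary at the first nonzero-difference point after the run,
    while touching without crossing (+, 0, +) yields none.  Grid endpoints
    are always the outer boundaries; identical mean curves give a partition
    with no interior boundary.
    """
    grid = group_a.grid
    if len(group_b.grid) != len(grid) or not np.array_equal(
        group_b.grid.values, grid.values
    ):
        raise ValueError("groups must share one D-grid")
    diff = group_a.mean_weights - group_b.mean_weights
    signs = np.sign(diff)
    boundaries = [grid.d_min]
    last_sign = 0.0
    for i, s in enumerate(signs):
        if s == 0.0:
            continue
        if last_sign != 0.0 and s != last_sign:
            d_cross = grid.values[i]
            if grid.d_min < d_cross < grid.d_max:
                boundaries.append(float(d_cross))
        last_sign = s
    boundaries.append(grid.d_max)
    return SubintervalPartition(np.asarray(boundaries), grid)


def sum_weights(
    weights: np.ndarray, partition: SubintervalPartition, k: int
) -> float:
    """Sum the per-grid-point weights over subinterval k."""
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (len(partition.grid),):
        raise ValueError("weights length must match the partition's grid")
    return float(weights[partition.membership(k)].sum())


def subinterval_sums(weights: np.ndarray, partition: SubintervalPartition) -> np.ndarray:
    """Vector of sum_weights over all subintervals (conserves the total)."""
    return np.array(
        [sum_weights(weights, partition, k) for k in range(partition.n_subintervals)]
    )


def delta_sadw(sadw_a: np.ndarray, sadw_b: np.ndarray) -> np.ndarray:
    """Per-subinterval difference of group sums of averaged weights (A - B)."""
    a = np.asarray(sadw_a, dtype=float)
    b = np.asarray(sadw_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("summaries cover different partitions")
    return a - b


def rank_abs_differences(deltas: np.ndarray, top_k: int | None = None):
    """Subintervals ordered by decreasing |delta|; ties keep the lower index.

    Returns ``(indices, values)`` of the top ``top_k`` entries (all, when
    ``top_k`` is None).
    """
    deltas = np.asarray(deltas, dtype=float)
    if top_k is None:
        top_k = deltas.size
    if top_k > deltas.size:
        raise ValueError("top_k exceeds number of subintervals")
    order = np.argsort(-np.abs(deltas), kind="stable")[:top_k]
    return order, deltas[order]


def ttest_sdw(
    group_a_values: np.ndarray, group_b_values: np.ndarray,
    subinterval: int = 0, welch: bool = False,
) -> TestResult:
    """Two-tailed two-sample t test on per-subject S_Dw of one subinterval.

    Uses the classical pooled-variance Student form by default; ``welch``
    switches to the unequal-variance form.  Degenerate zero-variance
    samples yield t=0, p=1 when the means agree and raise otherwise.
    """
    a = np.asarray(group_a_values, dtype=float)
    b = np.asarray(group_b_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 subjects")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return TestResult(subinterval, 0.0, 1.0, a.size, b.size)
        raise ValueError(
            "zero within-group variance with unequal means: t is undefined"
        )
    t, p = scipy.stats.ttest_ind(a, b, equal_var=not welch)
    return TestResult(subinterval, float(t), float(p), a.size, b.size)


def summarize_groups(
    group_a: GroupSpectra, group_b: GroupSpectra,
    partition: SubintervalPartition | None = None,
) -> tuple[WeightSummary, list[TestResult]]:
    """Full two-group comparison: partition (computed from the group means
    unless supplied), S_aDw per group, dS_aDw, per-subject S_Dw, and one
    t test per subinterval.  No multiple-testing correction is applied; the
    number of tests equals the number of subintervals."""
    if partition is None:
        partition = find_crossovers(group_a, group_b)
    sadw_a = subinterval_sums(group_a.mean_weights, partition)
    sadw_b = subinterval_sums(group_b.mean_weights, partition)
    sdw_a = np.vstack(
        [subinterval_sums(s.weights, partition) for s in group_a.spectra]
    )
    sdw_b = np.vstack(
        [subinterval_sums(s.weights, partition) for s in group_b.spectra]
    )
    summary = WeightSummary(
        partition=partition, sadw_a=sadw_a, sadw_b=sadw_b,
        sdw_a=sdw_a, sdw_b=sdw_b, delta=delta_sadw(sadw_a, sadw_b),
    )
    tests = [
        ttest_sdw(sdw_a[:, k], sdw_b[:, k], subinterval=k)
        for k in range(partition.n_subintervals)
    ]
    return summary, tests


def spectrum_peaks(spectrum: Spectrum, min_weight: float = 0.0):
    """Locate spectral peaks as contiguous runs of positive weight.

    Each run is summarized by its weight-weighted geometric-mean location
    (centroid in log D) and its total weight; runs are returned sorted by
    decreasing total weight.  Runs with total weight <= ``min_weight`` are
    dropped.  Returns ``(locations, weights)`` arrays.
    """
    w = spectrum.weights
    d = spectrum.grid.values
    locs, tots = [], []
    i = 0
    n = w.size
    while i < n:
        if w[i] > 0:
            j = i
            while j < n and w[j] > 0:
                j += 1
            tot = w[i:j].sum()
            if tot > min_weight:
                log_c = float(np.sum(w[i:j] * np.log10(d[i:j])) / tot)
                locs.append(10.0**log_c)
                tots.append(float(tot))
            i = j
        else:
            i += 1
    order = np.argsort(-np.asarray(tots), kind="stable") if tots else np.array([], int)
    return np.asarray(locs)[order], np.asarray(tots)[order]
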
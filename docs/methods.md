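# Methods

## Signal model and inversion

A voxel's (or ROI's) diffusion-weighted signal at b-value `b` is modelled
as a non-negative mixture of mono-exponential decays,

    I_n(b) = Σ_j W_j · exp(−b·D_j),

over a fixed grid of candidate diffusion coefficients `D_j`. The grid is
logarithmic with 200 points spanning [10⁻⁸, 10⁻¹] mm²/s (constant ratio
10^(7/199) ≈ 1.0844 between neighbours); b-values are in s/mm² so the
product b·D is dimensionless. The model makes no assumption about the
number of compartments — the fitted weight vector W is the "spectrum",
and any structure (peaks, bands) emerges from the data.

The inversion is regularized non-negative least squares:

    W(μ) = argmin_{W≥0} ‖A·W − I_n‖² + μ·WᵀW,

solved exactly as plain NNLS (Lawson–Hanson, via `scipy.optimize.nnls`)
on the augmented system [A; √μ·I] against [I_n; 0]. The identity between
the augmented residual norm and the penalized objective is algebraic and
is asserted in the test suite.

### Choosing μ: χ²-inflation targeting

With χ²(μ) = ‖A·W(μ) − I_n‖²/σ², the regularization weight is chosen so
that

    χ²(μ*) = (1 + α)·χ²(0),        α = 0.09 by default,

i.e. the fit is allowed to get 9% worse than the unregularized optimum
in exchange for a smoother, lower-energy spectrum — a level suited to
low-SNR data. Since χ²(μ) is monotone non-decreasing in μ (verified
empirically on geometric μ ladders in the tests), the target is found by
geometric expansion of an initial bracket [10⁻⁸, 1] followed by
bisection on log μ. Convergence is declared when the achieved ratio is
within `mu_tolerance` (absolute, default 10⁻³) of 1 + α; the search is
capped at `max_iterations` (default 100) and raises a convergence error
reporting the last bracket otherwise. Note the ratio χ²(μ)/χ²(0) is
independent of σ², so μ selection does not depend on the noise-variance
estimate; σ² (used only for reporting absolute χ²) defaults to the mean
squared residual of the unregularized fit and can be overridden with a
background-ROI or ground-truth value — the estimator the original
acquisition used is not recoverable, so an explicit input is the honest
interface.

Degenerate inputs: when the unregularized relative residual is below
0.1% the curve is effectively noise-free (only grid-resolution misfit
remains); there is no noise floor to inflate, and `select_mu` refuses
with a message directing the caller to μ = 0. With α = 0 the fit
degenerates to plain NNLS. Fitted weights are **not** renormalized to
sum to one: published group tables of this statistic sum to ≈1.09, so
raw fitted weights are the comparable quantity.

## Curve denoising

Voxel-level curves are smoothed (optionally; default on for voxel-wise
fitting, off for ROI means, which are already averaged over many voxels)
by a multiscale local-polynomial filter: Savitzky–Golay cubic fits of
the log-intensity at dyadic windows of 5 and 9 samples, averaged across
scales, exponentiated back, with the b=0 sample reset to its input
value. Working in log-intensity matches the near-log-linear local
structure of exponential decays and guarantees positivity. On noise-free
multi-compartment curves the smoother deviates by <1% of the normalized
signal scale at every point; fidelity is measured absolutely because the
decay tail underflows to values where relative error is meaningless. The
smoother is a pluggable callable, so a different transform can be
substituted without touching the pipeline.

## Group comparison

Per-subject spectra (all on one grid) are averaged pointwise within each
group. Crossover points — grid locations where the sign of the
difference of group-mean spectra strictly changes — partition the D-axis;
zero-difference runs are collapsed (a sign change across a run yields
one boundary at the first nonzero point after it; touching without
crossing yields none), and boundaries snap to grid points. Grid-point
membership in subintervals is half-open [lower, upper), the last
subinterval closed, so the per-subinterval sums conserve the total
weight exactly.

Per subinterval: S_aDw (sum of group-mean weights, one per group),
ΔS_aDw (mutant-like minus control-like), and per-subject S_Dw. S_Dw is
compared with a two-tailed pooled-variance Student t test (Welch
available behind a flag); no multiple-comparison correction is applied,
mirroring the analysis this package reimplements — the number of tests
is reported so users can correct downstream. The partition can also be
supplied externally (e.g. transcribed boundaries) and reused voxel-wise,
since a study derives it once from group means.

Physical interpretation helpers: the Stejskal–Tanner relation
b = γ²G²δ²(Δ − δ/3) (G in Gauss/cm converted internally to T/m; γ
defaults to the proton value 2.675×10⁸ rad·s⁻¹·T⁻¹ and is overridable,
so printed b-values are matched to ~0.1% rather than bit-exactly), and
the Einstein length sqrt(2DΔ) in μm, which translates a D-band into the
tissue length scale it probes.

## Synthetic data

The generator emulates the study conditions the pipeline was designed
for: a 30-point b-value schedule from 0 to 858,022 s/mm² (b=0 plus 29
log-spaced values from 10² — only the count and range of the original
schedule are known, so interior spacing is a package choice and no
analysis may depend on it); groups of 7 (mutant-like) and 8
(control-like) subjects; a four-compartment base mixture with
diffusivities at the four main control-cord spectral peaks (1.1×10⁻⁶,
1.47×10⁻⁵, 1.2×10⁻⁴, 6.08×10⁻⁴ mm²/s) and fractions (0.12, 0.24, 0.35,
0.29) apportioned like the control group's published band sums; 10%
multiplicative log-normal between-subject jitter on fractions
(renormalized — keeps fractions positive and unit-sum); Rician noise
(magnitude MRI) with σ = 1 and the b=0 amplitude scaled to the target
SNR, default 30, matching the low-SNR regime of ultra-high-b
acquisitions. Gaussian noise is available for oracle tests with
closed-form means. Group effects are additive shifts of a targeted
D-band's total fraction, with untargeted compartments rescaled
proportionally; direction-dependent (parallel vs transverse) diffusion
can be emulated by supplying two mixtures per tissue — no tensor
machinery is involved.

What the phantoms do **not** emulate: realistic cord anatomy and partial
voluming beyond discrete mixtures, spatially correlated noise, coil
profiles, eddy/motion effects, or continuous diffusivity distributions.
Passing tests therefore demonstrate correctness of the inversion and
statistics under the stated generative model, not performance on real
tissue.

## Numerical choices

- NNLS: `scipy.optimize.nnls` (deterministic active-set).
- μ search bracket [10⁻⁸, 1], expansion factor 10, bisection on log μ.
- Crossover detection uses exact sign changes of the floating-point mean
  difference; identical means give a trivial (single-subinterval)
  partition rather than an error.
- Ranking of |ΔS_aDw| breaks ties by lower subinterval index (stable
  sort).
- Zero within-group variance in the t test: t = 0, p = 1 when means
  agree; an error otherwise (the statistic is undefined).
- Voxel fits that fail (unnormalizable or all-zero signal,
  non-convergence) are flagged per voxel and logged, never silently
  dropped; maps carry NaN there and in the background.
- Library code draws no randomness; every simulation takes an explicit
  seed, and all stochastic tests are seeded.

## Problem sizes

Validation uses desk-scale simulations chosen as the smallest sizes at
which the checked properties are stable: 100 seeded curves for the
χ²-inflation and peak-recovery checks, 40 replicate null studies
(≈350 pooled tests) for type-I calibration, and 50 replicate perturbed
studies for the detection-power check. The type-I acceptance band
(1–12%) around the nominal 5% allows for binomial noise at that count
plus the selection effect of testing inside data-derived crossover
subintervals.

## Known limitations

- The diffusion-coefficient grid bounds are fixed by configuration, not
  estimated; compartments outside [d_min, d_max] alias onto the edges.
- NNLS spectra are sparse by nature; peak "width" reflects
  regularization, not a physical distribution width.
- The crossover partition depends on sample means and hence on sample
  size; small groups give unstable interior boundaries (the package
  supports reusing a fixed partition for that reason).
- Rician bias is simulated but not corrected for; at SNR ≳ 30 its effect
  on the normalized curve is small except in the deep tail.
- The t test treats subjects as exchangeable units; no covariates,
  no hierarchical structure.
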
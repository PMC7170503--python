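# dwspect

Multiexponential diffusion-spectrum analysis of multi-b-value
diffusion-weighted MRI decay signals.

At b-values far beyond the mono-exponential regime (here up to
~8.6×10⁵ s/mm²), tissue water signal decays as a mixture of many
exponential components. `dwspect` inverts such decay curves onto a
spectrum of diffusion coefficients, and compares the spectra of two
groups (e.g. a transgenic disease model vs wild-type controls) through
data-driven subintervals of the diffusion axis. It was built for ex vivo
spinal-cord studies of ALS-model (SOD1^G93A) mice, but applies to any
multi-compartment decay data — ROI-averaged curves or whole 4-D NIfTI
stacks.

## Model

The normalized signal `I_n(b) = I(b)/I(0)` is modelled as

    I_n = A·W,    A_ij = exp(−b_i·D_j),    W ≥ 0,

with `D` a 200-point logarithmic grid over [10⁻⁸, 10⁻¹] mm²/s. The
spectrum `W` is estimated by regularized non-negative least squares:

    argmin_{W≥0}  ‖A·W − I_n‖² + μ·WᵀW,

where the energy-penalty weight μ is tuned iteratively until the
regularized χ² misfit exceeds the unregularized one by a fixed fraction
α (default 9%):

    χ²_reg(μ) = (1 + α)·χ²_nonreg.

Group comparison: per-subject spectra are averaged within each group;
"crossover points", where the two group-mean spectra invert their
ordering, partition the D-axis into subintervals. Within each
subinterval the sum of averaged weights (S_aDw) per group, its group
difference (ΔS_aDw), and per-subject sums of weights (S_Dw) are
computed, and S_Dw is compared between groups with a two-tailed Student
t test. Voxel-wise S_Dw maps localize the differences anatomically.

Because no raw MRI data ship with the package, a synthetic-data module
generates decay curves, 4-D phantoms and two-group studies from known
compartment mixtures under Rician noise, giving every pipeline stage a
ground truth.

## Worked example

Simulate a 7-vs-8-subject study in which the mutant-like group loses
0.05 of its signal fraction in the [6.01×10⁻⁶, 4.20×10⁻⁵] mm²/s band,
fit every subject, and compare the groups:

```python
import dwspect as dw

schedule = dw.default_schedule()                # 30 b-values, 0 … 858,022 s/mm²
grid = dw.make_d_grid(200, 1e-8, 1e-1)
design = dw.build_design_matrix(schedule, grid)

spec = dw.GroupStudySpec(band_deltas={(6.01e-6, 4.20e-5): -0.05}, seed=42)
curves_a, curves_b, truth = dw.simulate_group_study(spec)

fit = lambda cs: [dw.select_mu(design, dw.normalize_signal(c).intensities,
                               dw.FitConfig(alpha=0.09)) for c in cs]
group_a = dw.average_spectra(fit(curves_a), "mutant")
group_b = dw.average_spectra(fit(curves_b), "control")

summary, tests = dw.summarize_groups(group_a, group_b)
for k in range(summary.n_subintervals):
    lo, hi = summary.partition.bounds(k)
    star = " *" if tests[k].significant else ""
    print(f"  [{lo:9.3g}, {hi:9.3g}] mm^2/s  SaDw {summary.sadw_a[k]:.4f} vs "
          f"{summary.sadw_b[k]:.4f}  dSaDw {summary.delta[k]:+.4f}  "
          f"p={tests[k].p:.4f}{star}")
```

Output:

```
  [    1e-08,  5.05e-08] mm^2/s  SaDw 0.0241 vs 0.0188  dSaDw +0.0053  p=0.6470
  [ 5.05e-08,   8.6e-07] mm^2/s  SaDw 0.0243 vs 0.0401  dSaDw -0.0158  p=0.0735
  [  8.6e-07,  6.52e-06] mm^2/s  SaDw 0.1074 vs 0.0787  dSaDw +0.0287  p=0.3239
  [ 6.52e-06,   0.00012] mm^2/s  SaDw 0.3279 vs 0.3972  dSaDw -0.0693  p=0.0111 *
  [  0.00012,  0.000841] mm^2/s  SaDw 0.4440 vs 0.3850  dSaDw +0.0590  p=0.1291
  [ 0.000841,   0.00812] mm^2/s  SaDw 0.0568 vs 0.0955  dSaDw -0.0387  p=0.1491
  [  0.00812,   0.00955] mm^2/s  SaDw 0.0001 vs 0.0000  dSaDw +0.0000  p=0.5759
  [  0.00955,    0.0168] mm^2/s  SaDw 0.0011 vs 0.0017  dSaDw -0.0006  p=0.7880
  [   0.0168,       0.1] mm^2/s  SaDw 0.0213 vs 0.0023  dSaDw +0.0190  p=0.0291 *
```

The crossover partition isolates the perturbed band inside the
[6.52×10⁻⁶, 1.2×10⁻⁴] mm²/s subinterval: the mutant-like group's weight
sum there is lower by 0.069 and the t test flags it (p = 0.011). The
starred top subinterval is a small-weight tail artifact of a single
noisy study — replicate-level behavior is what the test suite checks.

A command-line interface mirrors the library (`dwspect fit-roi`,
`fit-voxels`, `partition`, `summarize`, `map`, `simulate`); every
subcommand writes a resolved-config YAML next to its outputs.

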
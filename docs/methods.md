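# Methods

This note records the model assumptions, parameter choices and numerical
conventions behind `ftirfp`, and what the synthetic validation does and
does not demonstrate.

## Preprocessing chain

Spectra are processed full-range (4000–600 cm⁻¹) in a fixed order:
baseline correction, area normalization, Savitzky–Golay (SG) second
derivative; the three analysis windows (3000–2800, 1800–1500,
1200–900 cm⁻¹) are cropped out of the finished derivative so SG edge
loss never falls inside a window.

**Baseline.** Default is the rubberband: subtract the lower convex hull
of (λ, A), computed by a monotone-chain scan and linear interpolation
between hull points. The corrected spectrum is ≥ 0 and invariant to
adding any affine function of λ. A linear (two-endpoint chord) option
exists; smooth baselines are in any case annihilated by the second
derivative, so downstream results are insensitive to this choice.

**Normalization.** The spectrum is scaled so the trapezoidal integral of
|A| over the full range is 1. Using |A| (rather than signed A) makes the
operation well defined for derivative-like inputs; the choice is exposed
(`normalize_absolute`). Normalization happens before region selection
because it is a whole-spectrum operation; all three band ratios are
invariant to it.

**Second derivative.** SG filtering fits a quadratic in a sliding
window and differentiates the fit, scaled by the true grid spacing
(units AU·cm²). Only points covered by a full window are kept. The
default window is 3 points (`sg_half_width=1`): the acquisition
software's "3 smoothing points" setting read literally, and the only
quadratic window for which the second derivative of a σ = 8 cm⁻¹
Gaussian band on a 1 cm⁻¹ grid stays within 1% of the analytic value
−A/σ² (a 7-point quadratic window attenuates it by ≈3.7%). For noisy
spectra the window should be widened — the ratio-recovery validation at
2% noise uses `sg_half_width=3`, because a 3-point second difference is
derivative-noise-limited there — at the price of band attenuation,
which cancels in intensity ratios when the bands compared have similar
widths. The filter is exact on polynomials up to the fit order and
linear in its input; a non-uniform grid is rejected with a pointer to
`resample_to_grid` (linear interpolation, no extrapolation).

## PCA readouts

PCA operates on the mean-centered (not variance-scaled) region matrix
via SVD; replicates enter as independent rows, matching how replicate
point clouds appear in scores plots. Explained variance per component
is 100·σᵢ²/Σσ². Signs are fixed deterministically (each loading row is
flipped so its largest-|·| element is positive) so runs are reproducible
across platforms. "Clean separation" on a component means the groups can
be bipartitioned with every sample's score sign matching its group's
side; a score of exactly 0 counts as nonpositive. Quadrants on a score
plane use the mathematical convention Q1=(+,+), Q2=(−,+), Q3=(−,−),
Q4=(+,−); samples with a zero coordinate are flagged on-axis and
excluded from purity. Loading peaks are strict local extrema above
`min_prominence` (default 0.1) of the row's maximum magnitude; maxima
characterize the positive score side, minima the negative side.

## Band table and ratios

The packaged band table maps literature wavenumbers (2959 → 914 cm⁻¹,
plus the olefinic 3013 band) to vibrational modes and biomolecular
assignments, including the approximate amide-I (80% ν(C=O), 10% δ(N–H),
10% ν(C–N)) and amide-II (60% δ(N–H), 40% ν(C–N)) compositions. Matching
uses a tolerance of 8 cm⁻¹ — the acquisition resolution — with distance
ties broken toward the lower wavenumber.

Peak intensity is the magnitude of the deepest local second-derivative
minimum below zero inside a ±15 cm⁻¹ window around the literature
target; the located extremum (not the fixed literature position) is
measured, so group-dependent shifts (e.g. 2925 vs 2916 cm⁻¹) are
followed without the window reaching neighboring bands. A window with
no negative local minimum is a hard "no peak" error; the carbonyl and
olefinic ratios accept `allow_zero=True` to report 0 instead, since a
genuinely absent band is biologically meaningful there. Ratios are
computed on the full-range derivative (the 3013 cm⁻¹ olefinic band lies
outside the 3000–2800 PCA window) and are invariant to positive scaling
of the spectrum.

## Statistics

All rank tests use midranks. Kruskal–Wallis H carries the tie correction
1 − Σ(t³−t)/(N³−N) and is referred to χ²(k−1). The many-to-one post hoc
is Dunn's rank z against a designated control with the pooled-variance
term N(N+1)/12 − Σ(t³−t)/(12(N−1)) and Bonferroni (default) or Šidák
family adjustment over k−1 comparisons; a parametric "Dunnett" after a
rank omnibus would be incoherent, so the rank analogue is used under an
explicit name. Mann–Whitney U reports min(Uₓ, Uᵧ); the exact two-sided
p doubles the lower tail of the tie-free null distribution (classic
count recurrence, admissible for n₁, n₂ ≤ 8 without ties — with ties it
falls back to the tie-corrected normal approximation with a 0.5
continuity correction and logs a notice). Welch's t uses the
Welch–Satterthwaite df. The normality screen is D'Agostino's K²
(χ²(2)); it annotates a parametric/nonparametric recommendation but
never gates the nonparametric branch, and needs n ≥ 8. Significance is
declared at p ≤ 0.05 (inclusive).

**Replicates.** Technical replicates of one sample are not independent
observations (they share the sample's biological state), so the pipeline
averages replicates per sample before testing by default
(`replicate_handling: average`); pooling them as observations is
available (`pool`) but inflates rank-test type-I error roughly 2–3× on
simulated null cohorts and is therefore not the default.

## Synthetic cohorts

The generator emulates the study's design: wavenumber range
4000–600 cm⁻¹, three technical replicates per sample, and groups defined
by band inventories. Spectra are sums of Gaussian bands plus a quadratic
baseline (coefficients redrawn per replicate in a normalized coordinate,
so its second derivative is negligible) plus white noise
(default 0.002 AU). Biological variability is a per-band lognormal
amplitude factor with cv 0.08, drawn once per sample and shared across
its replicates. Defaults: 4 samples per group, 2 cm⁻¹ grid spacing
(finer than the 8 cm⁻¹ instrument resolution so derivative
discretization error stays well below test tolerances).

Scenario effects encode the study's qualitative findings as ground
truth: `coriell` gives the long-repeat group its CH₂ band at 2916
(others 2925 cm⁻¹) and CH₃ at 2953 (others 2959 cm⁻¹), a reduced 1747
ester carbonyl and an extra parallel-β-sheet amide-I band at 1628 cm⁻¹,
with a milder carbonyl reduction in the intermediate group; `neurolab`
elevates C–H stretch amplitudes in the severe-onset groups and the 1747
carbonyl in the infantile/congenital-like groups; `null` makes all
groups identical. Effect sizes are synthetic choices (the source data
report no quantitative effect sizes) calibrated once so the `coriell`
scenario reproduces the qualitative significance pattern.

The five ratio bands share one width (σ = 9 cm⁻¹) so SG attenuation
cancels exactly in every ratio. Ground-truth ratios are computed from
the closed-form second derivative of the band sum — the minimum within
each ±15 cm⁻¹ search window — which accounts for neighboring-band
overlap (an isolated band contributes A/σ² at its center); with zero
noise and zero variability the pipeline reproduces these within 2%
(derivative discretization only).

**What passing does not show.** The generator has Gaussian band shapes
(no Voigt/Lorentzian tails), no water-vapor or CO₂ lines, no ATR
penetration-depth dispersion, no scattering artifacts, and band-position
jitter is off by default. Passing its tests validates the pipeline's
numerics and the qualitative discrimination logic, not instrument-level
robustness on real fibroblast spectra.

## Validation problem sizes

The test suite and `scripts/acceptance.py` use: 5000 null cohorts
(3 groups × 10 samples × 3 replicates) for the type-I rate; 100 seeded
cohorts per scenario for the discrimination fractions; 50 seeds for the
noisy ratio-recovery medians; exhaustive enumeration up to n₁ = n₂ = 6
for the exact Mann–Whitney oracle; 10 random 6×40 matrices for the PCA
eigendecomposition cross-check. These sizes keep the whole validation at
a few minutes on one CPU while leaving the binomial/Monte-Carlo margins
of every asserted fraction comfortably wider than their standard errors.

## Known limitations

* The rubberband baseline is O(n) per spectrum but assumes an ascending
  dense grid; sparse or very short spectra (< 3 points) are rejected.
* Exact Mann–Whitney is enumeration-based and restricted to n₁, n₂ ≤ 8;
  larger samples use the normal approximation.
* Band assignment is nearest-neighbor within a fixed tolerance; it does
  not deconvolve overlapping bands or fit band shapes.
* The quadrant readout depends on PCA sign conventions; the packaged
  deterministic convention makes runs reproducible but quadrant labels
  are not comparable across different software.
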
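# Methods

## Model

The core quantity is the luminance of a surface patch viewed through a
linear polarizer at filter angle θ (degrees; ±90° = minimum-transmission
axis vertical). For partially linearly polarized reflected light this is
a 180°-period sinusoid,

    L(θ) = a · sin(2(θ + φ)) + b,

with amplitude a ≥ 0, baseline b > 0, and phase φ. The degree of linear
polarization is derived from the fitted extrema, d = (Lmax − Lmin)/(Lmax
+ Lmin) = a/b; the phase encodes the dominant polarization plane, with
φ = −45° meaning luminance peaks at θ = ±90°, i.e. predominantly
horizontally polarized light.

**Phase units.** φ is reported in *filter-angle* degrees on [−90°, +90°)
— the argument of the sinusoid is 2(θ + φ), not 2θ + φ. Only this
convention makes "peaks at ±90°" correspond to −45°, places horizontal
(−45°) and vertical (+45°) polarization symmetrically about 0, and gives
φ a 180°-periodic circular topology matching the physics (a polarization
plane has no sign). All phase differences are computed as shortest arcs
on that 180° circle.

**Fitting.** The model is linear in (a·cos2φ, a·sin2φ, b) on the basis
{sin2θ, cos2θ, 1}, so the least-squares fit is closed-form
(`numpy.linalg.lstsq`), global and deterministic; an iterative nonlinear
fit of the same model can only reproduce it, which the tests verify to
1e−8 with a multi-start `scipy.optimize.curve_fit` oracle. Negative
amplitudes are canonicalized to a ≥ 0 by a 90° phase shift. At a = 0 the
phase is undefined and reported as 0. The fit needs ≥ 4 samples at ≥ 3
angles distinct mod 180°; the rank of the design matrix is checked
rather than the angle list, so replicate endpoints count once.

**Fit quality and gating.** `fit_r` is the Pearson correlation between
the 7 fitted and 7 observed luminances. Phase analyses are gated on
`fit_r > critical_r(0.05, df)` for *both* stripe classes, with
df = n_points − 1 (= 6 for the protocol), giving the criterion r > 0.707.
Two caveats are deliberate and documented rather than "fixed":

* df = 6 is the convention of the field protocol, not the textbook
  residual df of a 3-parameter fit (which would be 4).
* `fit_r` is a fit-vs-data correlation of a model with two harmonic
  regressors, so under a pure-noise null its square follows
  Beta(1, (n−3)/2) = Beta(1, 2), and a single class passes r > 0.707
  for ≈ 25% of noise-only series (≈ 6% for the both-classes gate) —
  not 5%. The gate is therefore a *fit-quality filter* that discards
  unreliable phases, not an α-level hypothesis test; the test suite
  pins its actual calibration against the closed-form Beta null.

**Degree edge cases.** d is clipped to 1 with a warning when the fit
implies negative luminance (a > b beyond fp tolerance); b ≤ 0 is an
error. d is scale-invariant, which is why unknown per-series exposure
factors are harmless as long as exposure is locked within a series
(enforced: analysis refuses `exposure_locked=False`).

## Segmentation

Each ROI window is split at the threshold maximizing between-class
variance over a 256-bin histogram of the window's own luminance range
(Otsu's criterion at graythresh granularity). The threshold is
recomputed per image — polarization swings white-stripe luminance by
tens of percent — while class *identity* is anchored to the image with
filter angle closest to 0° and propagated by spatial agreement, so
labels cannot swap across the series. Ties in the variance curve (exact
across runs of empty bins) resolve to the lowest threshold, with a 1e−9
relative tolerance absorbing floating-point plateau noise; the
convention is `values ≥ threshold` → white. An ROI is excluded, not
errored, when any image lacks two usable classes: a class below 2% of
pixels, or Michelson contrast between class means below 0.05 (an ROI
inside a single stripe splits only noise). Constant windows raise.

ROI tracking is an optional convenience (field practice is manual
matching on coat fiducials): normalized cross-correlation of the
first-image patch over a ±search_radius window, warning when the peak
sits on the search boundary. Config-specified offsets override tracking.
Note that perfectly periodic stripes are translation-invariant along
their own axis; tracking needs real texture, which the generator can
supply (below).

## Acuity model

A fly's view from distance D is emulated by convolving each *full-frame*
image with an isotropic Gaussian and only then cutting ROIs, avoiding
window-edge artifacts. The acceptance function subtends `acuity_deg`
(default 1°, blowfly-like) at the observer; projected into the capture
image this is width_px = acuity_deg × pixels_per_degree × D /
capture_distance. "Width" is interpreted as FWHM by default (the
standard parameterization of ommatidial acceptance functions), σ =
width/2.3548, with a `sigma` convention switch since the term is
ambiguous. Boundary handling is reflective padding, which conserves mean
luminance and avoids dark-edge bias. Defaults: pixels_per_degree = 89.5
(the calibrated field value at 300 mm focal length), capture distance
50 m (field range 35–101 m), distance grid {1, 2, 5, 10, 20, 30, 50} m.

At each distance the pipeline re-extracts class means with the
*original* unblurred-image masks (the field procedure), refits the
sinusoid per class and for the mask-free pooled ROI, and averages
Michelson contrast over filter settings. Expected shape on synthetic
scenes: contrast decays monotonically while resolvable; the black/white
degree gap collapses at the same range; the pooled degree stays at the
luminance-weighted mixture value (b_b·d_b + b_w·d_w)/(b_b + b_w) for
equal phases. Numerical caveat: reflective padding leaves a residual
pseudo-contrast of order 1e−3 once stripes are fully unresolvable
(the mirrored stripe pattern is not periodic across the border), so
monotonicity tests treat values below 0.005 as floor noise rather than
asserting strict decrease into the floor.

## Synthetic scenes and cohort

The generator renders exactly the fitted model per pixel class —
black/white stripes on a rectangular target over a uniform background,
each class with its own (b, d, φ) — plus, optionally: 1-px linear edge
feathering; a static multiplicative log-normal albedo texture
(`texture_sd`), identical across filter angles, which rescales b per
pixel but leaves d and φ untouched (it emulates pelage/vegetation
graininess and makes tracking well-posed); and additive Gaussian sensor
noise clipped at 0. Using the fit model as forward model is a design
choice: the field method measures only this sinusoid, so parameter
recovery is the meaningful test surface, and full Mueller-calculus
rendering would add nothing testable. What the generator consequently
does *not* emulate: hair-fibre specularity and Brewster-angle geometry,
depth structure, motion blur, heat shimmer, or non-Gaussian sensor
noise — so passing tests certify the measurement chain, not field
photography.

Defaults chosen once for the study conditions: luminance baselines 60
(black), 160 (white), 110 (background) arbitrary linear units; degrees
0.25/0.15/0.10 with shared phase −45°; stripe period 16 px; sensor
noise default 0 in the dataclass, with the analysis drivers using 3.2
(2% of the white baseline — the magnitude is not specified by the field
protocol and is a free parameter).

The cohort generator runs 21 subjects × 7 ROIs through the *full*
pipeline (render → segment → fit), with per-ROI white degree lognormal
around 0.12 (log-sd 0.35), d_black = 1.46 × d_white, per-subject phase
with 3° per-class jitter, sunlit ROIs (60%) scaled ×1.3, and 10
coat/background pairs at design ratio 2.0 — the structure of the field
cohort's reported statistics, used as generator design targets. With 2%
noise the measured medians land on the design values to within
Monte-Carlo error (bootstrap CIs in the acceptance tests). Note the
synthetic cohort is cleaner than field data: essentially all ROIs pass
the significance gate, versus a minority in the field, because
field-scale nuisance variation (shading, hair geometry, movement) is
deliberately absent.

## Statistics

Paired black-vs-white comparisons use the Wilcoxon signed-rank test
(cross-checked against a sign-flip permutation oracle in the tests) and
Pearson correlation; the relative degree difference is reported under
both denominator conventions ((d_b − d_w)/d_w and /d_b) since the
convention is ambiguous; the headline number uses the white denominator.
Phase agreement is Pearson correlation of phases plus a paired t-test on
wrapped differences, on gated ROIs only. Group summaries report
box-plot statistics (quartiles, t-based 95% CI of the mean, 1.5×IQR
outliers). Coat-vs-background comparison reports per-pair ratios, the
median ratio and a paired t-test. Mixed-effects ANOVA/ANCOVA over
subjects is out of scope by design — the study table is exported as CSV
so any such model can be fitted externally.

## Problem sizes

Test and acceptance runs use 128×128-px scenes (64×64 for the cohort),
500-replicate Monte-Carlo grids for parameter recovery, 200 random
histograms / 100 random fit instances for the oracle-equivalence
checks, and a 21×7 cohort; the whole suite completes in a few seconds
on one core. These sizes were chosen as the smallest at which the
Monte-Carlo assertions have comfortable margins.

## Known limitations

* The forward model's realism is intentionally limited (see above);
  absolute field numbers are design targets for the synthetic cohort,
  not reproductions of field measurements.
* Otsu masks on heavily blurred images are reused verbatim (field
  procedure), so at extreme blur the "class means" sample overlapping
  mixed pixels; the resulting convergence of class degrees is the
  intended behaviour, but per-class values there should not be
  over-interpreted.
* Tracking assumes pure translation between exposures; rotation or
  deformation of the subject is not modelled.
* TIFF is the only input format; raw camera decoding is upstream of
  this package.
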
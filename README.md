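# polstripe

Rotating-polarizer photometry of striped animal coats: quantify the
polarized-light signature of high-contrast pelage (the motivating case is
plains zebras photographed in the field) and model how visible the stripes
and their polarization are to a low-acuity insect observer such as a
host-seeking horse fly.

## The measurement

A scene is photographed N times in quick succession through a linear
polarizing filter rotated to a known angle θ per exposure (protocol: 7
images, θ = −90°…+90° in 30° steps, with the replicate ±90° endpoints
providing a repeat-reliability estimate). Exposure is locked within the
series, so pixel values are linear luminance up to one unknown scale
factor. For a partially linearly polarized patch, luminance traces a
180°-period sinusoid of the filter angle:

    L(θ) = a · sin(2(θ + φ)) + b,      a ≥ 0

with amplitude *a*, baseline *b*, and polarization phase φ ∈ [−90°, +90°)
in filter-angle degrees (φ = −45° ⇔ luminance peaks at θ = ±90° ⇔
predominantly horizontally polarized light — the component biting flies
orient to). The model is linear in (a·cos2φ, a·sin2φ, b), so the fit is a
closed-form harmonic regression. The degree of linear polarization follows
from the fitted extrema:

    d = (Lmax − Lmin) / (Lmax + Lmin) = a / b ∈ [0, 1],

and stripe visibility is the Michelson contrast
(L_white − L_black)/(L_white + L_black) averaged over filter settings.
Black/white stripe pixel sets come from per-image Otsu thresholding
(256-bin between-class-variance maximization) inside tracked rectangular
ROIs. Phase comparisons are gated on fit quality for both classes
(r > 0.71 at df = 6 for the 7-point protocol), because φ is unreliable
when *d* is small. A compound-eye observer at distance D is emulated by
convolving each image with a Gaussian of angular FWHM 1° scaled to D,
then refitting with the original stripe masks.

Because no field photographs ship with the package, a synthetic-scene
generator renders striped targets on a vegetated background whose
per-class luminance follows the same sinusoid with known (b, d, φ),
plus sensor noise and albedo texture — so every stage is testable by
parameter recovery.

## Worked example

The numbered drivers under `analysis/` run the whole chain on synthetic
data and write tables under `results/`:

```
$ python analysis/02_fit_polarization.py --seed 1
shoulder: d_black=0.251 (true 0.25), d_white=0.150 (true 0.15), phase=(-45.2, -44.9) deg, contrast=0.453, gated=True
flank:    d_black=0.250 (true 0.25), d_white=0.150 (true 0.15), phase=(-45.1, -45.0) deg, contrast=0.453, gated=True
rump:     d_black=0.250 (true 0.25), d_white=0.150 (true 0.15), phase=(-45.1, -45.1) deg, contrast=0.452, gated=True
max |d - d_true| across ROIs/classes: 0.0006
```

Each ROI's black and white stripes refit to the generating degrees and to
the shared −45° phase (horizontally polarized light) to within the sensor
noise; all ROIs pass the significance gate.

```
$ python analysis/03_distance_sweep.py --seed 1
 dist (m)  contrast  d_black  d_white  d_pooled
        1     0.395    0.235    0.153     0.177
        5     0.122    0.190    0.168     0.178
       10     0.004    0.178    0.177     0.178
       50    -0.001    0.146    0.146     0.146
```

With distance, stripe contrast collapses (invisible beyond ~10 m for this
stripe width) and the black/white degree difference vanishes at the same
range — but the pooled coat polarization persists: at long range the coat
is a polarization beacon without stripes. (The mild decline of the pooled
degree at 20–50 m is the weakly polarized background bleeding into the
ROI under extreme blur.)

```
$ python analysis/04_cohort_comparison.py --seed 1
147 ROI pairs analyzed
median relative d difference (vs white): 46.0% (design 46%), Wilcoxon p = 7.2e-26
phase correlation on gated ROIs: r = 0.99, mean |phase diff| = 3.4 deg, paired t p = 0.18
coat vs background (10 pairs): median ratio 2.00 (design 2.0), paired t = 13.65, p = 0.000
```

A 21-subject cohort pushed through the full pipeline recovers its design
ratios: black stripes 46% more polarized than white, phases tightly
correlated, and the coat twice as polarized as adjacent vegetation.

The same pipeline is scriptable via the `polstripe` CLI
(`simulate | analyze | sweep | report`) driven by a single TOML config;
see `polstripe --help`. Real data enter as per-angle 16-bit TIFFs listed
in a `[series]` manifest.

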
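# Methods

## Particle model

A protein particle dried on mica is modelled as a **spherical cap**: the
part of a sphere of radius R protruding a height h above the surface,
0 < h ≤ 2R, with height profile z(ρ) = h − R + √(R² − ρ²). Its radius at
half height is r = √(R·h − h²/4), and its molecular volume is taken as
the spherical-segment estimate

    Vm = (π h / 6) (3 r² + h²)        [nm³]

evaluated at the half-height radius. This is the quantity AFM
single-particle studies report; it is an estimate, not the geometric cap
volume, and the synthetic generator defines each particle's ground-truth
volume by this same formula so that the measurement chain has an exact
oracle. Cap shape is parameterised by the aspect ratio α = h/R ∈ (0, 2];
at fixed α the volume is Vm = (π α² R³/6)(3 + α/4), giving R in closed
form from a target volume.

Volume additivity underlies stoichiometry: a complex of m copies of
receptor A and n of receptor B is predicted at m·V_A + n·V_B. Real AFM
volumes of complexes can undershoot strict additivity (interface burial,
tip effects); a configurable packing-loss fraction (default 0) accounts
for this if needed.

## Synthetic scans

The generator emulates the features of dry tapping-mode scans of purified
receptor on mica that matter to the analysis:

- **Particles**: volumes drawn per mixture component from a normal
  distribution truncated at zero; centres placed by rejection sampling at
  a minimum centre-to-centre separation (default 80 nm), at least one base
  radius plus two pixels from the field edge.
- **Background**: white Gaussian pixel roughness (default RMS 0.3 nm),
  per-scanline DC offsets (SD 1 nm) and a global plane tilt
  (0.005 nm/nm) — the minimal model of the artifacts line flattening must
  remove.
- **Geometry**: 2 μm × 2 μm fields. The default raster is 1024 × 1024
  (1.95 nm/pixel) so that the smallest particles span well over five
  pixels at half height; the study-scale fixture uses 50 such fields with
  40 particles each (~2000 particles), and the pipeline demo uses six
  512 × 512 fields to keep its runtime at a few seconds.
- **Populations**: the default two-component mixture is 58% free receptor
  (417 ± 60 nm³) and 42% complex (1174 ± 120 nm³), with aspect 0.1026 so
  the 417 nm³ particle is 3 nm tall — typical for a dried membrane
  receptor.
- **Tip convolution** is off by default, matching the idealisation of the
  volume formula; an optional grey-scale dilation with a spherical tip is
  provided to study the broadening it causes (it increases apparent r and
  hence volume).

Not emulated: cantilever dynamics, drift, humidity, liquid imaging,
amplitude/phase channels. Passing tests therefore demonstrate the
correctness and calibration of the measurement chain under the stated
noise model, not robustness to every instrumental artifact of real scans.

## Flattening and background statistics

Each scan line gets a polynomial (default order 1) fitted to its
background pixels — pixels more than 3 robust SDs **above** the running
fit are excluded iteratively, so particles do not drag the fit — and
subtracted; a global least-squares plane over background pixels is then
removed and the background median set to zero.

Background statistics are computed from the pixels below the upper decile
(particles occupy the top of the height distribution) with the truncation
bias of that selection removed under a Gaussian noise model: the median
of the lower 90% sits at the 45th percentile of the noise
(−0.12566 σ), and the median one-sided deviation below it spans
0.62975 σ. Without these order-statistic calibrations the baseline is
biased low by ~0.13 σ, which propagates directly into every apex height.

## Grain detection and measurement

Pixels above baseline + k·RMS (default k = 5) are segmented with
8-connectivity. Per grain:

- a provisional apex is taken from a lightly smoothed copy (Gaussian,
  σ = 1 px) so a single noise spike cannot masquerade as the summit;
- the **half-height region** is the connected set of pixels ≥ baseline
  + h/2 containing the apex, found on a window grown until the region no
  longer touches its border; r is its equivalent-disk radius
  √(area/π) and `area` its area;
- the apex height is then **refined by a cap-model average**: raw pixels
  within 0.7 r of the region centroid are averaged and the exact
  spherical sag mean(R − √(R² − ρ²)) added back, with R recovered from
  the provisional (h, r). The raw maximum instead rides on the upper tail
  of the pixel noise (bias ≈ +0.2–0.9 nm at SNR 10) and the smoothed
  maximum loses the profile curvature; the model average is unbiased to
  ~1% with per-particle scatter near the matched-filter floor
  (≈ 1.5–2% at SNR 10).

Quality-control flags mark grains whose h or r would be biased, and
flagged grains are excluded from volumetrics by default: `edge` (bounding
box within 2 px of the border — truncated profile), `small` (footprint
below 4 px or apex below 1 nm — for these the half-height contour sits
inside the noise floor, so only the thresholded footprint is recorded),
`eccentric` (half-height region eccentricity > 0.95 — an ideal cap is
circular), and `merged` (more than one regional maximum with prominence
above 2·RMS inside the half-height region — two particles fused into one
grain, for which the single-particle volume formula is invalid). A
`keep` policy measures merged grains anyway.

Conventions: pixel indices are 0-based, physical coordinates are
pixel-centre positions (index × pixel size), areas are pixel counts ×
pixel size². r is measured from the half-height area contour rather than
a 1-D profile cut; the two agree for ideal caps and the area contour is
rotationally robust for noisy ones.

## Histogram fitting

Volumes are binned into uniform half-open bins [lo, hi) (final bin
closed), default width 50 nm³ — about ten bins across the free-receptor
peak at study scale; the default range runs from 0 to the maximum volume
rounded up to a bin multiple, so counts are conserved. One or two
Gaussians A·exp(−(v−μ)²/2σ²) are fitted to the raw bin counts (a
histogram-curve fit, uniform weights) by bounded nonlinear least squares,
with initial means at the highest maxima of a lightly smoothed histogram
and up to five seeded randomized restarts. Choosing k is the caller's
decision; an advisory R²/BIC comparison between k = 1 and k = 2 is
attached to pipeline reports.

Peak-mean **standard errors** come from a heteroscedasticity-robust
sandwich covariance (J′J)⁻¹ J′VJ (J′J)⁻¹ with V = diag(fitted counts):
bin counts are Poisson, so their variance equals their mean, and the
naive least-squares covariance understates peak-position uncertainty.
With the sandwich, peak-shift z-statistics between independent fits are
calibrated (empirical z SD ≈ 0.95; naive covariance gives ≈ 1.5).

Degenerate outcomes are errors, never silent: fewer than 3k non-empty
bins is a precondition failure, a fitted σ below half the bin width is a
degenerate fit, and non-convergence after the restart budget raises with
diagnostics attached.

The proportion above a cut-off c is, by fitted area,
Σᵢ Aᵢσᵢ(1 − Φ((c−μᵢ)/σᵢ)) / Σᵢ Aᵢσᵢ, or the raw count fraction; both are
reported. A cut-off outside the fitted range sets a warning flag rather
than failing.

## Stoichiometry assignment

All compositions with 0 ≤ counts ≤ max (default 3) per reference
component, not all zero, are enumerated. Each gets
z = |peak − predicted| / √(peak SE² + Σ countᵢ²·ref SEᵢ²) and is accepted
at z ≤ 3 (the only printed uncertainties being peak SEs, a 3-SE
consistency rule is the natural convention). Ranking is by ascending z
with ties broken by fewest total subunits (parsimony); the ranking is
invariant under a common rescaling of all volumes and uncertainties.

## Concentration

Particles are counted inside an inclusive volume window [lo, hi] around a
species' peak (e.g. 403–431 nm³ for the free receptor, 991–1209 nm³ for
the complex) and divided by the total scanned area. Molarity is
density × total mica area × 10⁶ / (elution volume × N_A), with
N_A = 6.02214076 × 10²³. The total wetted mica area is a required user
input (default 10⁷ μm² ≈ a 3.6 mm spot from a 50 μl deposit); 100%
adsorption is assumed, so M underestimates the true solution
concentration when adsorption is incomplete — a known bias direction, not
corrected. Replicate estimates (e.g. independent purification series)
aggregate as mean ± SD/√n.

## Pipeline

A single YAML configuration (validated field-by-field; unknown keys are
rejected by name) drives image/table input or simulation, detection,
fitting, proportions, stoichiometry and concentration. Stage failures
abort with the stage name and preserve the partial report. With a fixed
seed the report is byte-reproducible; the output location is omitted from
the config echo so reruns into different directories still compare equal.
Per-stage grain counts before and after filtering are logged so the
"n analyzed" of any figure-style summary is always recoverable.

## Numerical and design notes

- Cap dimensioning from (volume, aspect) is closed-form; populations are
  reproducible from integer seeds (per-image seeds spawned via
  `SeedSequence`).
- Placement retries are bounded (200 per particle); failure names the
  number placed.
- Detection thresholds in RMS multiples make the detector invariant to
  the absolute noise scale; on noise-free images the threshold falls back
  to "above baseline".
- The half-open binning convention puts a value on an interior edge into
  the upper bin; this is asserted, not assumed.
- assign_stoichiometry with zero combined uncertainty gives z = 0 for an
  exact match and z = ∞ otherwise, so exact additivity is still ranked
  first.

## Known limitations

- No tip-deconvolution: fitted means from tip-convolved data are biased
  high; the generator's tip mode exists to quantify, not correct, this.
- The merged-grain detector needs a resolvable dip between summits; two
  particles closer than about a pixel merge into a single clean-looking
  grain and are not flagged.
- The volume formula's accuracy for real proteins rests on the cap
  idealisation; deviations (faceting, flattening during drying) shift
  absolute volumes but largely cancel in peak *ratios*.
- Molarity accuracy is limited by the adsorption-efficiency and
  wetted-area assumptions, which rescale all estimates multiplicatively.
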
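# Methods

This note records the models implemented in `ebfilm`, the defaults they
ship with, and the numerical and design choices made where more than one
defensible option existed. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Dose engine

The dose rate around the source is the TG-43 point-source product
`S_K · Λ · (r0/r)² · g_p(r) · F(r,θ)` with `r0` = 1 cm. Assumptions:

* **Point source.** No line-source geometry function; adequate at the
  1–3 cm radii the film studies probe.
* **Tabulated `g_p` and `F`, bilinear interpolation.** Linear in `r` and
  `θ` between knots, exact at knots, *no extrapolation* — queries outside
  a table raise `TableRangeError` rather than guessing. Continuity and
  agreement with a brute-force bilinear oracle are regression-tested.
* **Angle convention.** θ is measured from the proximal end of the source
  (0° up the catheter, 180° through the dome tip). Much TG-43 literature
  measures from the tip; convert with θ_tip = 180° − θ.
* **Units.** `S_K·Λ` is carried in cGy/h (the conventional per-hour
  constants); `delivered_dose` divides by 3600 and credits only
  `max(0, t − t_ramp)` with the electronic source's ramp-up
  `t_ramp` = 2 s by default.

Because the vendor's tables for this source/tandem combination are not
public, `example_source_model(offset)` generates *synthetic stand-in*
tables, labelled as such: `g_p(r) = exp(−0.15 (r − 1))` (quasi-exponential
falloff beyond inverse square, magnitude typical of ~50 kVp x rays in
water, radii 0.25–8 cm), and `F` built from three Gaussian angular dose
deficits — dome tip (centred 160°, strongest for the 0 mm dwell offset),
oblique wall (115°, growing with pull-back), and shaft (10°) — with a mild
linear radial scaling and exact transverse normalization. Default
`S_K` = 1000, `Λ` = 50 cGy/(h·U) put ~13.9 cGy/s at the reference point,
so study-scale exposures take tens of seconds of beam time.

## Synthetic film scans

The generator produces raw 48-bit RGB rasters at 150 dpi (16 bits per
channel, low pixel value = high dose, as a transmission scanner darkens
with dose), with a paired un-irradiated background scan drawn from the
same scanner model, and the full ground truth in the image metadata.

**Film response.** Per channel, inverted pixel value follows
`PV(D) = a·exp(−bD) + c` with `a < 0`. Defaults (red −30000, 0.0030 cGy⁻¹,
42000; green −32000, 0.0006, 40000; blue −25000, 0.00025, 43000) order the
channel sensitivities as radiochromic film does — red fastest-saturating,
blue slowest — and keep the red channel's useful range near its 0–6 Gy
window.

**Scanner model.** Three imperfections:

* *Lateral nonuniformity*: a single-period cosine gain field over a
  virtual 216 × 297 mm scanner bed on which every film is centred (films
  are scanned in a flatbed's central region). The amplitude is specified
  as the statistic it must reproduce — the relative SD of the landscape
  profile of a 5 × 4 in un-irradiated film with the 4 mm border excluded —
  0.0077 by default; a smaller along-scan amplitude (0.002) models the
  lamp-direction variation. Smaller study films correctly see only the
  flatter central part of the field.
* *Additive Gaussian pixel noise*, default SD 100 PV per channel (~0.2%
  of the un-irradiated signal), a realistic figure for a warmed-up
  flatbed.
* *Optional constant offset* (default 0).

Gain is applied multiplicatively to the raw raster, then offset and
noise, then rounding to uint16. Fixed seed ⇒ bit-identical output.

**Geometries.** Calibration films sit orthogonal to the axis 13 mm beyond
the dome tip; the lateral profile is the point-source falloff at that
geometry scaled so the film centre receives exactly the prescribed dose
(this makes centre-finding and the 2 mm ROI meaningful). Polar films
contain the source axis; the marked dwell position is a geometry
parameter, so the film's lateral placement is configurable rather than
fixed. Pixels nearer the source than the radial table minimum are flagged
invalid — a film abutting the source always contains some — while pixels
beyond the table maximum raise a range error naming the pixel (or are
masked with `on_out_of_range="mask"`). Azimuthal films are a four-film
array orthogonal to the axis on the proximal side, spaced exactly 1 cm,
threaded over the tandem through a punched hole (default radius 2.5 mm);
the hole scans at full transmission and the hole-plus-4 mm annulus is
flagged invalid, mirroring the cut-edge de-lamination rule. An optional
multiplicative modulation `1 + A·cos(φ − φ0)` can be injected for
recovery tests.

**What is *not* emulated** — and therefore what passing tests do not
show about real film: post-exposure darkening kinetics, water-immersion
optical-density drift, film de-lamination beyond the fixed exclusion
margins, energy-spectrum response shifts with depth, scanner warm-up
drift, and film-placement/rotation errors (source position is exact in
the synthetic geometry; a dedicated property test instead *injects* a
0.5 mm position error and checks that anisotropy agreement improves with
radius).

## Film analysis chain

Order of operations, per scan pair: invert (v → 65535 − v) → 3×3 mean
smoothing → background subtraction → calibration curve. Choices:

* **Smoothing edges:** mirror padding; invalid pixels are excluded from
  each neighbourhood and the mean renormalized. (Inversion before or
  after a linear mean filter is equivalent; inversion-first is used.)
* **Background:** for *calibration points*, a scalar — the 5 mm-square
  ROI mean of the smoothed background at the analysis centre. For *dose
  maps*, pixel-wise subtraction of the smoothed background raster is the
  default (`background_mode="pixelwise"`), because a scalar cannot
  represent the scanner's lateral field and would leave a tilt of a few
  hundred PV across the film; the scalar mode remains available. Negative
  net values clamp to zero (warned).
* **Centre finding:** column- and row-collapsed profiles of the
  background-corrected raster, each conditioned with a symmetric 5 mm
  moving average; the peak is the centroid of the plateau within 25% of
  the profile's dynamic range of the maximum. The wide plateau makes the
  centroid of a symmetric exposure nearly noise-free at the faintest
  calibration level while exact ties still resolve to their midpoint; a
  plateau spanning more than half the extent (a flat film) is a detection
  error.
* **ROI means:** a pixel belongs to an ROI when its *centre* falls inside
  the shape (2 mm circle for calibration readings, 5 mm square for
  background); no area weighting. ROIs touching invalid pixels or the
  film edge are errors, not silent truncations.
* **Exclusion:** 4 mm from every film edge or cut (hole) is invalid
  throughout, by pixel-centre distance.
* **Calibration fit:** least squares on `net_pv = a·exp(−bD) + c` via
  Levenberg–Marquardt, initialized from the closed-form log-linear
  estimate (`c₀ = 1.05·max(net)`, regression of `ln(c₀ − net)` on dose;
  the mirrored branch handles decreasing data). Three restarts with
  scaled rate constants before a `FitError` carrying diagnostics.
  Requires ≥ 4 points, ≥ 3 distinct doses; an all-equal response is
  degenerate (`b` unidentifiable). Monotonicity is enforced post-fit
  (`b > 0`). R² = 1 − SS_res/SS_tot.
* **Inversion:** `D = −ln((net − c)/a)/b`, defined strictly between the
  zero-dose value and the asymptote; outside, a `SaturationError` names
  the violated bound. Raster conversion flags saturated pixels and pixels
  mapping beyond 1.2× the calibrated dose maximum (beyond that the curve
  is unsupported by data; the 20% margin keeps readings *at* the top
  calibration level valid under noise), and clamps sub-background pixels
  to dose 0.
* **Channel selection:** red `[0, 600)`, green `[600, 3500)`, blue
  `≥ 3500` cGy — half-open so the boundary doses go to the higher-dose
  channel, a deterministic reading of the "0–6 Gy / 6–35 Gy / >35 Gy"
  sensitivity ranges.

One systematic effect is worth naming: the 2 mm calibration ROI averages
a slightly lower dose than the film-centre peak (the synthetic anisotropy
is steep near 180°), so the fitted `b` carries a uniform effective-dose
scale relative to the generator's truth. Because the identical ROI
protocol both builds and applies the curve, the scale cancels in dose
recovery and exactly cancels in anisotropy ratios; the noiseless
pipeline-recovery test (< 0.1%) probes with the same protocol for this
reason.

## Anisotropy extraction

Polar: `F(r,θ) = D(r,θ)/D(r,θ0)` with per-radius transverse
normalization (θ0 = 90°), sampled from the dose map by bilinear
interpolation; all four bracketing pixels must be valid. Default
comparison grid: 10° steps (20–160° in the round-trip tests, where the
extremes stay clear of the exclusion borders). Percent error uses the
reference model in the denominator; reports give mean and max per
distance and channel.

Azimuthal: dose at each angle (mean over a ±2° arc, 5 samples, to reduce
pixel noise) normalized to the angular mean, so the profile's mean is 1
by construction. Angle zero is the film's +x axis, counter-clockwise.
Default sampling: 24 angles × radii {1, 2, 3} cm. Dispersion statistics
use the *population* SD (small n, and a descriptive — not inferential —
summary): relative SD per (film, radius), film-averages per radius, the
overall mean, and the per-(film, angle) SD across radii maximised over
angles and averaged over films.

The default azimuthal prescription sets the beam timer so the nearest
film receives 1000 cGy at 1 cm from the axis; this keeps every sampled
radius on every film inside the calibrated dose range of the default
truth (a hotter prescription would saturate the nearest film's inner
radius past the calibration ceiling).

## Uncertainty budget

Components are relative standard uncertainties in percent, treated as
uncorrelated Type-B terms and combined in quadrature with no coverage
factor. The calibration-curve-fitting slot is scenario-dependent (3.8%
restricting each channel to its sensitive range, 7.8% using all channels
everywhere; explicit values in between are accepted); the film-orientation
component ships excluded because all films are scanned in one
orientation. Totals are reported unrounded — the shipped table gives
8.05% and 10.54%, rendered 8.0–10.5 at one decimal; note that quadrature
of already-rounded one-decimal inputs can differ in the last digit from
a total computed on unrounded data.

## Beam quality

HVL comes from normalized transmission-vs-aluminum readings by
*log-linear* interpolation between the bracketing points — exact for
mono-exponential attenuation and standard in kV dosimetry (a linear
interpolation would bias high). The curve must start at (0, 1), be
strictly increasing in thickness and non-increasing in transmission.
Filter attenuation is `100·(1 − filtered/open)`; an anomalous
filtered > open reading returns its negative percentage with a warning
rather than hiding it.

## Problem sizes and determinism

Default study sizes — 12 calibration levels on 50.8 mm films, one
70 × 50 mm polar film, four 70 × 70 mm azimuthal films, all at 150 dpi —
were chosen so a full study runs in about a second and the complete
acceptance recomputation (including a 20-repeat noisy calibration) in
well under a minute, while every ROI still spans ≥ 100 pixels. All
randomness in a study descends from its single seed through independent
child streams; outputs (curve JSON, CSVs, manifest) are byte-identical
across reruns, and the manifest records the seed, a configuration hash
and the package version.

## Known limitations

* The stand-in source tables are *shaped* like the physical problem but
  are not vendor data; absolute numbers derived from them (e.g. the
  effective-dose scale above) characterize the pipeline, not the source.
* Scalar background mode cannot represent lateral scanner structure;
  it exists for protocol fidelity and comparison, not accuracy.
* No multi-channel (triple-channel) dose disentanglement, no
  lateral-response correction maps, no spectral/beam-hardening modelling
  of the titanium, and no treatment-planning-system comparison — all
  outside the package's measurement-chain scope.
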
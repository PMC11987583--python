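# Methods

## The physical model

A fluorophore is excited with probability ∝ cos²θ between the illumination
polarisation and its absorption dipole (single-photon photoselection), and
its emission is polarised along the emission dipole, normally near-parallel
to the absorption dipole.  If fluorophores bound to a fibre rotate freely and
fast relative to the fluorescence lifetime, these effects average out: the
Perrin relation R = R0/(1 + τf/τrot) (implemented as `perrin_anisotropy`)
gives a measured anisotropy near zero for τrot ≪ τf.  When the structure,
linker and dye conspire to constrain rotation, emission stays polarised along
the fibre axis and — under polarised excitation — fibre brightness becomes a
function of fibre orientation.  On the image level this acts as a real,
positive frequency-space operator: it rescales the Fourier *amplitude* of
each orientation while leaving phases (structure) untouched.  Because
photoselection is a cos² law, the operator's angular dependence at each
spatial frequency is limited to second order in θ, which is what makes a
two-number-per-ring description (γc, γs) complete.

## Estimators

**Pair mode.**  For polarisation-resolved images H and V of the same field,
`anisotropy_image_pair` forms FA = 1 + (|Yv| − |Yh|)/(|Yv| + |Yh|) from the
2-D DFT magnitudes (G-factor applied to one channel first; FA = 1 where both
magnitudes vanish).  FA ∈ [0, 2]; values above 1 mean vertically-polarised
emission dominates that scale and orientation.  Discarding phase makes the
measure insensitive to channel misalignment — an integer shift changes the
moments not at all, sub-pixel shifts only at the interpolation-error level.

**Single mode.**  `anisotropy_image_single` uses FA = |Y|.  The moments then
mix polarisation bias with intrinsic structural alignment, which is why the
correction needs a calibration image that is structurally unaligned.

**Ring moments.**  `extract_ring` samples FA at nearest pixels on a ring
(ellipse for non-square images, the ring index living on the major axis),
with the angular sample count growing as ⌈2πr⌉ so arc spacing stays ≈1 px.
`anisotropy_moments` computes γc = Σ FA·cos 2θ / Σ FA and the sine analogue.
A profile 1 + A·cos 2θ therefore has γc = A/2; the factor 2 reappears when a
profile is reconstructed from its moments.  The DC ring is always excluded.
A truncated Fourier-series fit of a ring profile (a0/2 + a2 cos 2θ +
b2 sin 2θ) is available on demand (`fit_ring_series`) but the moments are the
primary summary.

**Angle conventions.**  Degrees, 0° along +columns, anticlockwise, period
180°.  Frequency-space angles use the same visual frame; the Fourier power of
fibres at real-space orientation θf lies at frequency angle θf + 90°, and all
reported angles are rotated back into the fibre frame.  Axial circular
statistics use the doubled-angle transform throughout.

## The correction (FouRD)

`calibration_spectrum` runs the single-image path on a calibration image
assumed to contain many randomly oriented fibres, so its angular moments
describe the excitation operator alone — an *assumption* the code cannot
verify (an intrinsically aligned calibration absorbs that alignment into the
"bias" and the correction would then remove real structure; a negative
control test documents this).  Optional n-point moving-average smoothing
(`smooth_spectrum`, shrinking windows at the ends) suppresses ring-level
estimation noise without reshaping the spectrum.  Spectra from several fields
of view can be averaged (`average_spectra`) when no single field can be
trusted to be unaligned; this also halves-to-thirds the estimation noise and
is used in the round-trip validation.

`build_inverse_operator` assigns every uncentred coefficient its exact
continuous (r, θ), rounds r to the nearest measured ring, and sets the value
to 1/max(1 + 2γc·cos 2θ + 2γs·sin 2θ, clamp).  Choices that matter:

* **Moment-to-profile factor 2.**  The moments are normalised second-order
  projections, so the ring profile they describe is 1 + 2γc cos 2θ +
  2γs sin 2θ; building the reciprocal from the bare moments would cancel only
  half the measured modulation.  The round-trip test (operator × its own bias
  profile ≡ 1 within 1%) pins this choice; `moment_scale` exposes it.
* **Clamp floor (default 0.05).**  Noise can push measured moments to where
  the reconstructed profile crosses zero; the denominator is floored rather
  than letting single coefficients blow up.  A warning reports when the clamp
  engages outside the unmodified low-ring zone.
* **Start radius (default 2) and DC** are left at exactly 1, so the lowest
  frequencies — background and, in patch-wise mode, the tile means — are
  never rescaled.  Rings beyond the measured range reuse the last moment pair
  (they are noise-dominated and near zero).

`correct_image` multiplies the image's DFT by the operator and returns the
real part of the inverse transform; phase preservation and exact energy
conservation under an identity spectrum are asserted in tests.

**Patch-wise mode** (`patchwise_correct`) tiles image and calibration
identically (non-overlapping tiles, last row/column absorbing the
remainder; tiles below 64 px are refused), runs the full
calibrate-invert-correct chain per tile and reassembles by direct placement.
Different low-frequency corrections in adjacent tiles create seam steps;
raising the start radius to ~5 with 3-point smoothing removes them without
measurably changing downstream angle maps.  `tile_seam_step` quantifies the
seams on the low-passed correction delta (corrected − original), where the
shared structure cancels.

A statsmodels-style front end wraps the estimation: `PolarisationModel(cal)`
`.fit()` returns `PolarisationResults` carrying the raw and smoothed spectra,
the implied polarisation axis (from the resultant of per-ring moment vectors,
which add coherently for a real bias and cancel for noise) with a
modulation-weighted standard error, the peak modulation, a bias-detection
flag based on the coherent mean moment (threshold 0.03), `summary()`,
`plot_spectrum()` and `correct()`.

## Alignment metrics

`patch_orientation` reduces a square window to the central second moments
μ20, μ02, μ11 of its centred Fourier magnitude.  The closed-form roots
a, b = (μ20+μ02)/2 ± √(4μ11² + (μ20−μ02)²)/2 are the eigenvalues of the
moment matrix (an eigen-decomposition oracle confirms this to 1e−8);
eccentricity e = √(1 − b²/a²) runs from 0 (isotropic) to 1 (perfectly
aligned) and the major-axis orientation, rotated 90°, gives the local fibre
angle.  b is clamped to [0, a] against floating-point excursions; zero
windows report e = 0 with an undefined (NaN) angle.  Windows are
mean-subtracted and Hann-tapered before the transform: the discontinuity at a
non-periodic window boundary otherwise leaks an axis-aligned cross into the
spectrum that biases angles towards 0°/90° and breaks the monotonicity of e
in true alignment.  `alignment_maps` slides complete windows (default 250 px,
50% overlap, border remainders dropped, no masking or thresholding) over the
image.

`spectrum_orientation_distribution` bins the whole-image Fourier magnitude
into 1° orientation bins over a ring range and normalises by the per-bin
pixel count (the integer frequency lattice fills wedges near the axes and
diagonals unevenly; without normalisation that lattice artefact alone
violates flatness for white noise).  Circular variance
V = 1 − |Σ w·e^{2iθ}|/Σw and the weighted axial mean (with an optional
90°-offset reporting frame) summarise it.  This emulates the orientation
summary of whole-spectrum tools such as CytoSpectre only approximately: no
spectral component separation is attempted.

Hypothesis tests: an axial Rayleigh test (finite-n corrected p) and a
two-sample Kuiper test (origin-invariant on the circle, Stephens' asymptotic
tail probability) are implemented in `fourd.circstats`.  Because 50%-overlap
windows share pixels, tests are run on the non-overlapping window subset
(`AlignmentMaps.independent_angles_deg`); using all windows would be
anti-conservative.

## The simulator

`simulate_field` draws n fibres with angles uniform on a configurable range
(restriction = intrinsic alignment), lengths uniform on [min, max], centres
uniform on the canvas; fibres may overlap and are clipped at borders.
`render_image` deposits each fibre as an anti-aliased 1-px line (bilinear
deposition of point samples every 0.5 px; flux = length × base_signal ×
polarisation factor), blurs with a Gaussian PSF, block-averages by the
downsampling factor (zero-padding right/bottom if needed), adds a constant
background, then Poisson noise, then additive Gaussian read noise — in that
order; the float output is left unclipped (quantisation to 16-bit TIFF clips
at 0 explicitly).  One master seed expands into separate geometry / Poisson /
Gaussian streams so a polarisation-resolved pair shares geometry but not
noise.  The orientation-dependent brightness operator has two forms —
1 + P·cos 2Δ (P ∈ [0, 1]) and 1 + P·cos²Δ (P ≥ 0) — and can be ramped
linearly across the field (strength × column/width) to emulate spatially
varying polarisation.  `simulate_polarised_pair` weights each fibre by
1 ± s·cos 2θf in the horizontal/vertical channel (emission parallel to the
fibre axis).

Default recipes:

| recipe | canvas | fibres | lengths | signal | blur σ | down | noise |
|---|---|---|---|---|---|---|---|
| `default_recipe` | 5000² | 50,000 | 50–250 px | 1000 | 13 px | 5× | Poisson + N(20, 2) |
| `matlab_recipe`  | 512² (var.) | density-matched | 50–150 px | 310 | 2.7 px FWHM | 1× | bg 10 + Poisson |
| `demo_recipe`    | 1024² | 5,243 | 20–100 px | 1000 | 3 px | 2× | Poisson + N(20, 2) |

`default_recipe` renders a 1000² image with an effective 100 nm pixel.
`matlab_recipe`'s base signal of 310 counts puts the blurred per-fibre peak at
≈10:1 over the shot-noise floor of the 10-count background.  `demo_recipe`
matches the full recipe's fibre density (0.3 fibre-px per px²) and its
structure band relative to Nyquist, at 1/100 the pixel count; the test suite
and round-trip validations use it (plus a 1024²-canvas/no-downsampling
variant) so that the whole suite runs in under a minute of simulation time.

What the simulator does **not** emulate: curved or branching fibres, 3-D
sectioning and out-of-focus background, fibre bundling, labelling-density
variation along fibres, detector pattern noise, and emission-side
(detection-path) polarisation bias.  Validation against it therefore shows
the estimators and the correction are self-consistent under the stated image
formation model, not that real collagen data meet that model.

## Analysis bands and problem sizes

Whole-image orientation summaries and calibration fits are evaluated over the
structure-bearing frequency band, rings 5 … N/(π·σ_eff) with σ_eff the
post-downsampling blur (`structure_band`): below ring 5 background dominates,
beyond the Gaussian MTF's e⁻² support only noise remains, and including
either merely dilutes orientation statistics.  Round-trip comparisons of
moment spectra use rings 5–50 of 3-point-smoothed single-image spectra and
compare *signed means* across rings: per-ring moment estimates carry
irreducible speckle noise (ring r holds ~2πr Rayleigh-distributed magnitudes,
sd(γ) ≈ 0.52/√(4πr)), which is incoherent across rings, whereas genuine bias
is coherent — the signed mean is the statistic that separates them at these
image sizes.

## Known limitations

* The calibration transfers only if acquired under the same conditions
  (fluorophore, labelling, chamber, objective, laser line) as the data; the
  operator is a joint property of microscope and label, not of the sample.
* Per-tile calibration needs tiles both small enough for constant
  polarisation and large enough for a representative orientation
  distribution; at 64–150 px tiles the per-tile spectra are estimation-noise
  dominated and patch-wise correction mainly buys seam-free *spatial
  tracking*, not lower per-tile residuals, until tiles hold a few hundred
  fibres.
* The second-order (cos 2θ) model is exact for single-photon photoselection
  with parallel absorption/emission dipoles; a non-zero inter-dipole angle
  leaves a residual the model does not capture.
* Correction at frequencies where signal is below the noise floor divides
  noise by the reconstructed profile, imprinting a weak inverse modulation
  there; restricting the fitted spectrum to the structure band avoids this.
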
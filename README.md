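# fourd — Fourier ring anisotropy and polarisation-bias correction for fibre images

Fluorescently labelled fibres (collagen gels, F-actin, and other filament
networks) can emit polarised fluorescence: when the fluorophore's rotation is
constrained by the structure and linker, emission dipoles align with the
fibre axis.  Under the polarised excitation typical of laser-based
microscopes, fibre brightness then depends on fibre *orientation* — fibres
parallel to the polarisation axis appear brighter.  Automated orientation
analysis (AFT, OrientationJ, CytoSpectre and similar) happily quantifies this
purely optical bias as "alignment", masking the true microarchitecture of the
sample.

This package implements, in Python:

* **Fourier ring anisotropy** — a per-spatial-frequency measure of
  orientation-dependent brightness.  For a polarisation-resolved image pair
  (horizontal/vertical detection) it forms the anisotropy image
  `FA = 1 + (|Yv| − |Yh|)/(|Yv| + |Yh|)` from the Fourier magnitudes, samples
  it around rings of radius *f*, and projects each ring onto cos 2θ / sin 2θ:

  γc(f) = Σθ FA(f, θ)·cos 2θ / Σθ FA(f, θ),  γs(f) likewise with sin 2θ.

  Because only magnitudes enter, the measure is robust to misalignment
  between channels (position lives in the phase).  A single unresolved image
  can be analysed the same way with `FA = |Y|`.

* **FouRD (Fourier ring depolarisation)** — image-level correction of
  excitation-polarisation bias.  From a calibration image of an intrinsically
  *unaligned* sample, the moment spectra describe the excitation operator
  alone; its reciprocal ring profile

  Y<sup>inv</sup>(f, θ) = 1 / (1 + 2γc(f)·cos 2θ + 2γs(f)·sin 2θ)

  is applied as a direct product in frequency space.  The operator is real
  and positive, so phases — structure — are untouched; only the relative
  brightness of orientations changes.  Spatially varying polarisation is
  handled by tiling (e.g. 7×7) with per-tile calibration, and tile-seam
  artefacts are suppressed by leaving rings below a start radius unmodified.

* **Alignment metrics** — AFT-style sliding-window analysis producing local
  fibre angle and an eccentricity score e = √(1 − b²/a²) ∈ [0, 1] from the
  central second moments of each window's Fourier magnitude, plus axial
  (doubled-angle) circular statistics and a whole-image orientation
  distribution of the power spectrum (a CytoSpectre-style summary).

* **A fibre-image simulator** — ground truth for all of the above: straight
  anti-aliased fibres with uniform or restricted orientations, an
  orientation-dependent brightness operator (`1 + P·cos 2Δ` or
  `1 + P·cos²Δ`, optionally ramped across the field), Gaussian PSF blur,
  block-average downsampling, and Poisson + Gaussian camera noise.

## Worked example

```python
import fourd as fd

# calibration image: unaligned fibres under polarised excitation (20% at 80°)
bias = fd.PolarisationSettings(angle_deg=80.0, strength=0.2)
calibration = fd.render_image(fd.simulate_field(fd.demo_recipe(seed=0)), bias, seed=0)

results = fd.PolarisationModel(calibration, smoothing=3).fit()
print(results.summary())

# correct an independently simulated image with the same bias
image = fd.render_image(fd.simulate_field(fd.demo_recipe(seed=1)), bias, seed=1)
corrected = results.correct(image)

pre = fd.alignment_maps(image, window_px=64)
post = fd.alignment_maps(corrected.as_image(), window_px=64)
print(f"dominant angle before: {fd.mean_orientation(pre.angles_deg):6.1f} deg "
      f"(circular variance {fd.circular_variance(pre.angles_deg):.3f})")
print(f"dominant angle after : {fd.mean_orientation(post.angles_deg):6.1f} deg "
      f"(circular variance {fd.circular_variance(post.angles_deg):.3f})")
```

prints

```
Polarisation calibration results
============================================
calibration shape           512x512
rings                       1..255
smoothing (points)          3
--------------------------------------------
polarisation axis (deg)        78.81  (se 1.16)
peak modulation               0.2889
coherent moment |mean γ|      0.0383
bias detected (>=0.03)          True
============================================
dominant angle before:   82.9 deg (circular variance 0.436)
dominant angle after :   64.8 deg (circular variance 0.730)
```

The fit recovers the simulated polarisation axis (78.8° vs the true 80°) from
the calibration image alone.  Before correction the window-angle map of an
*isotropic* fibre field is pinned near the polarisation axis with a low
circular variance (0.436 — spuriously "aligned"); after correction the
dominant angle is gone and the circular variance rises towards the isotropic
limit of 1.  `results.plot_spectrum()` plots the γc/γs spectra, raw and
smoothed.

The same pipeline is available from a shell:

```sh
fourd simulate --recipe recipe.json --out img.tif --truth truth.csv --seed 1
fourd spectrum --pair H.tif V.tif --g-factor 1.13 --out spec.csv
fourd correct  --image img.tif --calibration cal.tif --out corrected.tif --tiles 7x7
fourd align    --image corrected.tif --window 250 --overlap 0.5 --out maps/
fourd end-to-end --out run/ --seed 1
```

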
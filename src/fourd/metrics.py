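"""Fibre-alignment quantification on images.

Two complementary summaries:

* Patch-wise Fourier analysis in the style of Alignment by Fourier Transform
  (AFT): for each sliding window the centred magnitude spectrum is reduced to
  its central second moments; the moment-matrix roots give an eccentricity
  e = √(1 − b²/a²) ∈ [0, 1] (0 isotropic, 1 perfectly aligned) and the
  semimajor-axis orientation gives the local fibre angle (the Fourier ellipse
  is perpendicular to the fibres, so the axis is rotated 90° back into the
  real-space frame).

* A whole-image orientation distribution of the Fourier power spectrum,
  summarised by axial circular variance and mean orientation — a deliberately
  approximate emulation of CytoSpectre-style whole-spectrum summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .circstats import circular_variance, mean_orientation  # noqa: F401  (re-export)
from .ring import Image2D

__all__ = [
    "PatchMoments",
    "EccentricityResult",
    "AlignmentMaps",
    "patch_moments",
    "patch_orientation",
    "alignment_maps",
    "spectrum_orientation_distribution",
    "structure_band",
    "circular_variance",
    "mean_orientation",
]


@dataclass(frozen=True)
class PatchMoments:
    """Central second moments of a normalised patch power spectrum."""

    mu20: float
    mu02: float
    mu11: float
    centroid: tuple[float, float]  # (x̄, ȳ) in (col, row-up) coordinates


@dataclass(frozen=True)
class EccentricityResult:
    eccentricity: float
    angle_deg: float  # semimajor-axis orientation in the real-space fibre frame; NaN if undefined
    a: float
    b: float
    moments: PatchMoments | None = None


@dataclass
class AlignmentMaps:
    angle_map: np.ndarray
    eccentricity_map: np.ndarray
    window_px: int
    overlap: float

    @property
    def angles_deg(self) -> np.ndarray:
        """Flat array of defined window angles."""
        flat = self.angle_map.ravel()
        return flat[~np.isnan(flat)]

    @property
    def independent_angles_deg(self) -> np.ndarray:
        """Angles from a non-overlapping window subset.

        Overlapping windows share pixels, so their angles are correlated;
        hypothesis tests (Rayleigh, Kuiper) on all windows would be
        anti-conservative.  This subsamples the map at the stride that makes
        windows disjoint.
        """
        step = max(1, math.ceil(1.0 / (1.0 - self.overlap)))
        flat = self.angle_map[::step, ::step].ravel()
        return flat[~np.isnan(flat)]


def patch_moments(weights: np.ndarray) -> PatchMoments:
    """Central moments μ20, μ02, μ11 of a non-negative weight image.

    Coordinates are x = column, y = −row so angles come out anticlockwise
    from the +x axis, matching the real-space convention.
    """
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    rows = np.arange(w.shape[0], dtype=float)[:, None]
    cols = np.arange(w.shape[1], dtype=float)[None, :]
    x, y = cols, -rows
    xbar = float((w * x).sum() / total)
    ybar = float((w * y).sum() / total)
    mu20 = float((w * (x - xbar) ** 2).sum() / total)
    mu02 = float((w * (y - ybar) ** 2).sum() / total)
    mu11 = float((w * (x - xbar) * (y - ybar)).sum() / total)
    return PatchMoments(mu20=mu20, mu02=mu02, mu11=mu11, centroid=(xbar, ybar))


def patch_orientation(patch: Image2D | np.ndarray, taper: bool = True) -> EccentricityResult:
    """Local alignment of one square patch from its Fourier magnitude.

    The roots of the second-moment matrix,

        a, b = (μ20 + μ02)/2 ± √(4μ11² + (μ20 − μ02)²)/2,

    equal its eigenvalues; e = √(1 − b²/a²) and the angle is the major-axis
    orientation rotated 90° into the fibre frame.  Floating point can push b
    marginally negative or above a, so b is clamped to [0, a] first.

    By default the patch is mean-subtracted and Hann-tapered before the
    transform: the discontinuity at a non-periodic patch boundary otherwise
    leaks an axis-aligned cross into the spectrum that biases both the angle
    (towards 0°/90°) and the eccentricity.  Set ``taper=False`` for the raw
    periodogram.
    """
    values = patch.values if isinstance(patch, Image2D) else np.asarray(patch, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("patch must be square")
    if values.shape[0] < 32:
        raise ValueError("patch side must be >= 32")
    if taper:
        hann = np.hanning(values.shape[0])
        values = (values - values.mean()) * np.outer(hann, hann)
    mag = np.fft.fftshift(np.abs(np.fft.fft2(values)))
    total = mag.sum()
    if total <= 0:
        return EccentricityResult(eccentricity=0.0, angle_deg=float("nan"), a=0.0, b=0.0)

    mom = patch_moments(mag)
    half_sum = 0.5 * (mom.mu20 + mom.mu02)
    half_disc = 0.5 * math.sqrt(4.0 * mom.mu11**2 + (mom.mu20 - mom.mu02) ** 2)
    a = half_sum + half_disc
    b = min(max(half_sum - half_disc, 0.0), a)
    if a <= 0:
        return EccentricityResult(eccentricity=0.0, angle_deg=float("nan"), a=a, b=b, moments=mom)
    ecc = math.sqrt(max(1.0 - (b / a) ** 2, 0.0))
    fourier_angle = 0.5 * math.atan2(2.0 * mom.mu11, mom.mu20 - mom.mu02)
    angle = (math.degrees(fourier_angle) + 90.0) % 180.0
    return EccentricityResult(eccentricity=ecc, angle_deg=angle, a=a, b=b, moments=mom)


def alignment_maps(img: Image2D, window_px: int = 250, overlap: float = 0.5) -> AlignmentMaps:
    """Sliding-window angle and eccentricity maps (AFT-style).

    Only complete windows are analysed (partial border windows dropped); no
    masking or thresholding is applied.  Default 250-px windows with 50%
    overlap.
    """
    m, n = img.shape
    if window_px > min(m, n):
        raise ValueError("window larger than image")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    stride = max(1, int(round(window_px * (1.0 - overlap))))
    r_starts = range(0, m - window_px + 1, stride)
    c_starts = range(0, n - window_px + 1, stride)
    angle = np.full((len(r_starts), len(c_starts)), np.nan)
    ecc = np.zeros((len(r_starts), len(c_starts)))
    for i, r0 in enumerate(r_starts):
        for j, c0 in enumerate(c_starts):
            res = patch_orientation(img.values[r0 : r0 + window_px, c0 : c0 + window_px])
            angle[i, j] = res.angle_deg
            ecc[i, j] = res.eccentricity
    return AlignmentMaps(angle_map=angle, eccentricity_map=ecc, window_px=window_px, overlap=overlap)


def spectrum_orientation_distribution(
    img: Image2D, r_min: int = 1, r_max: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Orientation histogram of the Fourier magnitude spectrum.

    Centred magnitudes over rings [r_min, r_max] (DC excluded) are
    accumulated into 1° orientation bins and normalised by the number of
    frequency-plane pixels per bin (the integer lattice fills wedges near the
    axes and diagonals unevenly, so raw sums carry a lattice artefact).  The
    result is the mean spectral magnitude per orientation, reported in the
    real-space fibre frame (frequency angles rotated by 90°).  Returns
    (bin centres on [0, 180), weights).
    """
    m, n = img.shape
    nyq = min(m, n) // 2 - 1
    if r_max is None:
        r_max = nyq
    if not 1 <= r_min <= r_max <= nyq:
        raise ValueError(f"ring range [{r_min}, {r_max}] outside [1, {nyq}]")
    mag = np.fft.fftshift(np.abs(np.fft.fft2(img.values)))
    mx = max(m, n)
    drow = (np.arange(m) - m // 2)[:, None] * (mx / m)
    dcol = (np.arange(n) - n // 2)[None, :] * (mx / n)
    radius = np.hypot(drow, dcol)
    fibre_angle = (np.degrees(np.arctan2(-drow, dcol)) + 90.0) % 180.0
    mask = (radius >= r_min) & (radius <= r_max)
    bins = np.floor(fibre_angle[mask]).astype(np.int64) % 180
    sums = np.bincount(bins, weights=mag[mask], minlength=180)
    counts = np.bincount(bins, minlength=180)
    weights = np.divide(sums, counts, out=np.zeros(180), where=counts > 0)
    return np.arange(180, dtype=float) + 0.5, weights


def structure_band(recipe) -> tuple[int, int]:
    """Ring band where the simulated optics retain structure.

    Low bound 5 excludes the background-dominated lowest frequencies; the
    upper bound N/(π·σ_eff) is the e⁻² support of the Gaussian MTF with the
    recipe's effective post-downsampling blur σ_eff = blur_sigma/downsample.
    """
    sigma_eff = recipe.blur_sigma_px / recipe.downsample
    n = min(recipe.canvas_px) // recipe.downsample
    upper = int(n / (math.pi * sigma_eff)) if sigma_eff > 0 else n // 2 - 1
    return 5, min(upper, n // 2 - 1)
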
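"""Fourier ring depolarisation (FouRD): frequency-space correction of
excitation-polarisation bias.

Polarised excitation over-represents fibres parallel to the polarisation
axis.  In frequency space this acts as a real, positive operator that scales
Fourier amplitudes by orientation while leaving phases (structure) untouched.
The operator is estimated from a calibration image of an intrinsically
unaligned sample of the same kind: with no structural alignment, the angular
modulation of its magnitude spectrum at each ring reflects only the
polarisation.  The per-ring moments (γc, γs) reconstruct the ring profile
1 + 2γc·cos2θ + 2γs·sin2θ, whose reciprocal is applied as a direct product in
frequency space (the factor 2 converts normalised second-order moments back
into the profile's modulation amplitude; a profile 1 + A·cos2θ has moment
A/2).  The lowest rings (below ``start_radius``) and DC are left unmodified,
which suppresses low-frequency seam artefacts in patch-wise correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .ring import (
    AnisotropySpectrum,
    Image2D,
    anisotropy_image_single,
    spectrum,
)

__all__ = [
    "CorrectionOperator",
    "PatchLayout",
    "CorrectedImage",
    "calibration_spectrum",
    "smooth_spectrum",
    "build_inverse_operator",
    "correct_image",
    "patchwise_correct",
    "tile_seam_step",
]

MIN_CALIBRATION_SIDE = 64  # below this there are too few rings to estimate


@dataclass
class CorrectionOperator:
    """Real positive frequency-space multiplier in uncentred layout."""

    values: np.ndarray
    start_radius: int
    source_spectrum: AnisotropySpectrum
    clamp_floor: float

    def __post_init__(self) -> None:
        if np.any(self.values <= 0):
            raise ValueError("operator values must be positive")


@dataclass(frozen=True)
class PatchLayout:
    """Non-overlapping tiling; the last row/column absorbs the remainder."""

    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("tiling counts must be >= 1")

    def edges(self, shape: tuple[int, int]) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
        m, n = shape
        hr, hc = m // self.n_rows, n // self.n_cols
        rows = [(i * hr, (i + 1) * hr if i < self.n_rows - 1 else m) for i in range(self.n_rows)]
        cols = [(j * hc, (j + 1) * hc if j < self.n_cols - 1 else n) for j in range(self.n_cols)]
        return rows, cols


@dataclass
class CorrectedImage:
    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def as_image(self) -> Image2D:
        return Image2D(values=self.values, metadata=dict(self.provenance))


def calibration_spectrum(
    calibration_img: Image2D, r_min: int = 1, r_max: int | None = None
) -> AnisotropySpectrum:
    """Single-image anisotropy spectrum of an unaligned calibration sample.

    With a large number of randomly oriented fibres the intrinsic structure
    contributes no second-order angular dependence, so the measured moments
    describe the excitation operator alone.  If the calibration sample is in
    fact aligned, that alignment is (wrongly) absorbed into the operator —
    the structural randomness is an assumption, not something this function
    can verify.
    """
    m, n = calibration_img.shape
    if min(m, n) < MIN_CALIBRATION_SIDE:
        raise ValueError(
            f"calibration image {m}x{n} too small (need >= {MIN_CALIBRATION_SIDE} px per side)"
        )
    return spectrum(anisotropy_image_single(calibration_img), r_min=r_min, r_max=r_max)


def smooth_spectrum(spec: AnisotropySpectrum, n_points: int) -> AnisotropySpectrum:
    """Centred n-point moving average of γc and γs (shrinking windows at the
    ends); n_points must be odd, n_points=1 is the identity."""
    if n_points < 1 or n_points % 2 == 0:
        raise ValueError("n_points must be odd and >= 1")
    if n_points == 1:
        return spec
    k = n_points // 2
    n = len(spec.frequencies)

    def avg(arr: np.ndarray) -> np.ndarray:
        out = np.empty_like(arr)
        for i in range(n):
            lo, hi = max(0, i - k), min(n, i + k + 1)
            out[i] = arr[lo:hi].mean()
        return out

    return AnisotropySpectrum(
        frequencies=spec.frequencies,
        gamma_c=avg(spec.gamma_c),
        gamma_s=avg(spec.gamma_s),
        mode=spec.mode,
        source_shape=spec.source_shape,
        n_samples=spec.n_samples,
    )


def _polar_grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Continuous (ring radius, frequency angle) for every uncentred
    coefficient, with elliptical scaling so the ring index lives on the major
    axis of non-square grids."""
    m, n = shape
    mx = max(m, n)
    drow = (np.fft.fftfreq(m) * m)[:, None] * (mx / m)
    dcol = (np.fft.fftfreq(n) * n)[None, :] * (mx / n)
    radius = np.hypot(drow, dcol)
    theta = np.arctan2(-drow, dcol)
    return radius, theta


def build_inverse_operator(
    spec: AnisotropySpectrum,
    shape: tuple[int, int],
    start_radius: int = 2,
    clamp_floor: float = 0.05,
    moment_scale: float = 2.0,
) -> CorrectionOperator:
    """Inverse excitation operator from a calibration spectrum.

    Every uncentred coefficient gets its exact continuous (r, θ); r is rounded
    to the nearest measured ring and the value is

        1 / max(1 + moment_scale·(γc(r)·cos2θ + γs(r)·sin2θ), clamp_floor).

    ``moment_scale=2`` reconstructs the ring profile's modulation from its
    normalised moments; rings below ``start_radius`` and DC are left at 1
    ("leaving the lowest frequencies unmodified"), and rings beyond the
    measured range reuse the last moment pair (the highest rings are
    noise-dominated and near zero anyway).
    """
    if clamp_floor <= 0:
        raise ValueError("clamp_floor must be positive")
    radius, theta = _polar_grid(shape)
    ring = np.rint(radius).astype(np.int64)

    f0 = int(spec.frequencies[0])
    idx = np.clip(ring - f0, 0, len(spec.frequencies) - 1)
    gc = spec.gamma_c[idx]
    gs = spec.gamma_s[idx]
    denom = 1.0 + moment_scale * (gc * np.cos(2 * theta) + gs * np.sin(2 * theta))
    values = 1.0 / np.maximum(denom, clamp_floor)
    unmodified = ring < max(start_radius, 1)  # includes DC
    values[unmodified] = 1.0
    if np.any(denom[~unmodified] < clamp_floor):
        warnings.warn(
            "measured moments imply a non-positive ring profile; denominator "
            f"clamped at {clamp_floor}"
        )
    return CorrectionOperator(
        values=values, start_radius=start_radius, source_spectrum=spec, clamp_floor=clamp_floor
    )


def correct_image(img: Image2D, op: CorrectionOperator) -> CorrectedImage:
    """Apply the inverse operator: FFT, direct product, inverse FFT.

    The operator is real and positive, so phases — and hence structure — are
    untouched; only the relative brightness of orientations changes.
    """
    if img.shape != op.values.shape:
        raise ValueError(f"image shape {img.shape} != operator shape {op.values.shape}")
    corrected = np.fft.ifft2(np.fft.fft2(img.values) * op.values).real
    return CorrectedImage(
        values=corrected,
        provenance={
            "start_radius": op.start_radius,
            "clamp_floor": op.clamp_floor,
            "mode": "whole-frame",
        },
    )


def patchwise_correct(
    img: Image2D,
    calibration_img: Image2D,
    layout: PatchLayout,
    start_radius: int = 2,
    smoothing: int = 1,
    clamp_floor: float = 0.05,
) -> CorrectedImage:
    """Estimate and apply the correction independently per tile.

    Handles spatially varying excitation polarisation: each tile of the
    calibration image yields its own spectrum and inverse operator, applied to
    the corresponding tile of the target image; tiles are reassembled by
    direct placement.  Tiles must be small enough that the polarisation is
    near constant across them but large enough to hold a representative
    spread of fibre orientations.  ``start_radius`` >= 2 suppresses
    low-frequency discontinuities at tile seams.
    """
    if img.shape != calibration_img.shape:
        raise ValueError("image and calibration must share dimensions")
    rows, cols = layout.edges(img.shape)
    if min(r1 - r0 for r0, r1 in rows) < MIN_CALIBRATION_SIDE or min(
        c1 - c0 for c0, c1 in cols
    ) < MIN_CALIBRATION_SIDE:
        raise ValueError(f"tiles smaller than {MIN_CALIBRATION_SIDE} px; use a coarser layout")

    out = np.empty(img.shape)
    for r0, r1 in rows:
        for c0, c1 in cols:
            cal_tile = Image2D(values=calibration_img.values[r0:r1, c0:c1])
            spec = calibration_spectrum(cal_tile)
            spec = smooth_spectrum(spec, smoothing)
            op = build_inverse_operator(
                spec, cal_tile.shape, start_radius=start_radius, clamp_floor=clamp_floor
            )
            tile = Image2D(values=img.values[r0:r1, c0:c1])
            out[r0:r1, c0:c1] = correct_image(tile, op).values
    return CorrectedImage(
        values=out,
        provenance={
            "start_radius": start_radius,
            "smoothing": smoothing,
            "clamp_floor": clamp_floor,
            "mode": f"patchwise-{layout.n_rows}x{layout.n_cols}",
        },
    )


def tile_seam_step(
    corrected: np.ndarray, original: np.ndarray, layout: PatchLayout, lowpass_sigma: float = 4.0
) -> float:
    """Largest intensity discontinuity the correction introduced at tile seams.

    Seam artefacts come from different low-frequency corrections applied to
    adjacent tiles, so they live in the correction delta (corrected −
    original) where the shared image structure cancels.  The delta is
    low-pass filtered (Gaussian, ``lowpass_sigma``) and the mean absolute
    difference between the pixel lines either side of each interior boundary
    is taken; the maximum over boundaries is returned.
    """
    delta = np.asarray(corrected, dtype=float) - np.asarray(original, dtype=float)
    smooth = gaussian_filter(delta, lowpass_sigma)
    rows, cols = layout.edges(delta.shape)
    steps = []
    for r0, _ in rows[1:]:
        steps.append(np.abs(smooth[r0 - 1, :] - smooth[r0, :]).mean())
    for c0, _ in cols[1:]:
        steps.append(np.abs(smooth[:, c0 - 1] - smooth[:, c0]).mean())
    return float(max(steps)) if steps else 0.0
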
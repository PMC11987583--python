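"""Fourier ring anisotropy: frequency-space quantification of orientation-
dependent brightness differences.

From a pair of polarisation-resolved images of the same field, the Fourier
anisotropy image

    FA = 1 + (|Yv| − |Yh|) / (|Yv| + |Yh|)

discards positional information (phase) and keeps only scale (ring radius r)
and orientation (angle θ around the ring).  Sampling FA around each ring and
projecting onto cos 2θ / sin 2θ gives the anisotropy moment spectra γc(f),
γs(f): how polarised the emission is at each spatial frequency.  A single
unresolved image can be analysed the same way using FA = |Y|, in which case
the moments mix polarisation bias with intrinsic structural alignment.

Angles in frequency space use the same visual convention as real space
(0° along +column, anticlockwise); note that the Fourier power of fibres at
real-space orientation θf lies along frequency angle θf + 90°.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Image2D",
    "FourierImage",
    "AnisotropyImage",
    "RingProfile",
    "AnisotropySpectrum",
    "DetectionCalibration",
    "PerrinParams",
    "forward_transform",
    "inverse_transform",
    "centre",
    "uncentre",
    "anisotropy_image_pair",
    "anisotropy_image_single",
    "extract_ring",
    "anisotropy_moments",
    "fit_ring_series",
    "spectrum",
    "perrin_anisotropy",
]


@dataclass
class Image2D:
    """Real-space grey-level grid, the unit of all I/O."""

    values: np.ndarray
    pixel_size: float | None = None  # physical size per pixel (nm), optional
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("Image2D requires a 2-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Image2D values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class FourierImage:
    """Complex frequency-space grid; the centred state is tracked explicitly."""

    values: np.ndarray
    centred: bool = False


@dataclass
class AnisotropyImage:
    """Real frequency-space anisotropy grid.

    mode "pair": values 1 + (|Yv|−|Yh|)/(|Yv|+|Yh|), bounded in [0, 2].
    mode "single": magnitudes |Y|, non-negative.
    """

    values: np.ndarray
    centred: bool
    mode: str  # "pair" | "single"

    def __post_init__(self) -> None:
        if self.mode not in ("pair", "single"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class RingProfile:
    radius: int
    thetas_rad: np.ndarray
    samples: np.ndarray
    series: tuple[float, float, float] | None = None  # (a0, a2, b2), on demand


@dataclass
class AnisotropySpectrum:
    """Per-ring anisotropy moments γc(f), γs(f)."""

    frequencies: np.ndarray
    gamma_c: np.ndarray
    gamma_s: np.ndarray
    mode: str
    source_shape: tuple[int, int]
    n_samples: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=np.int64)
        self.gamma_c = np.asarray(self.gamma_c, dtype=np.float64)
        self.gamma_s = np.asarray(self.gamma_s, dtype=np.float64)
        if not (len(self.frequencies) == len(self.gamma_c) == len(self.gamma_s)):
            raise ValueError("spectrum arrays must have equal length")
        if len(self.frequencies) > 1 and not np.all(np.diff(self.frequencies) > 0):
            raise ValueError("frequencies must be strictly increasing")

    @property
    def modulation(self) -> np.ndarray:
        """Per-ring modulation amplitude of the reconstructed ring profile,
        2·√(γc² + γs²) (a profile 1 + A·cos2(θ−φ) has moment amplitude A/2)."""
        return 2.0 * np.hypot(self.gamma_c, self.gamma_s)

    def implied_angle_deg(self, rings: slice | np.ndarray | None = None) -> float:
        """Real-space polarisation axis implied by the moment resultant:
        ½·atan2(Σγs, Σγc) is the dominant frequency-space angle, rotated 90°
        back into the fibre frame."""
        gc, gs = self.gamma_c, self.gamma_s
        if rings is not None:
            gc, gs = gc[rings], gs[rings]
        freq_angle = 0.5 * math.atan2(float(np.sum(gs)), float(np.sum(gc)))
        return (math.degrees(freq_angle) + 90.0) % 180.0


def average_spectra(specs: list["AnisotropySpectrum"]) -> "AnisotropySpectrum":
    """Average moment spectra from several fields of view.

    For calibration samples that cannot be guaranteed structurally random in
    a single field, averaging spectra over multiple diverse fields suppresses
    both estimation noise and residual alignment of any one field.
    """
    if not specs:
        raise ValueError("need at least one spectrum")
    first = specs[0]
    for s in specs[1:]:
        if not np.array_equal(s.frequencies, first.frequencies):
            raise ValueError("spectra must share the same ring axis")
    return AnisotropySpectrum(
        frequencies=first.frequencies,
        gamma_c=np.mean([s.gamma_c for s in specs], axis=0),
        gamma_s=np.mean([s.gamma_s for s in specs], axis=0),
        mode=first.mode,
        source_shape=first.source_shape,
        n_samples=first.n_samples,
    )


@dataclass(frozen=True)
class DetectionCalibration:
    """Relative detection efficiency of the two polarisation channels."""

    g_factor: float = 1.0
    which_divided: str = "horizontal"  # channel divided by g_factor

    def __post_init__(self) -> None:
        if self.g_factor <= 0:
            raise ValueError("g_factor must be positive")
        if self.which_divided not in ("horizontal", "vertical"):
            raise ValueError("which_divided must be 'horizontal' or 'vertical'")


@dataclass(frozen=True)
class PerrinParams:
    r0: float
    tau_f: float  # fluorescence lifetime, ns
    tau_rot: float  # rotational diffusion time, ns

    def __post_init__(self) -> None:
        if self.tau_f <= 0 or self.tau_rot <= 0:
            raise ValueError("lifetimes must be positive")


def perrin_anisotropy(p: PerrinParams) -> float:
    """Measured anisotropy R = R0 / (1 + τf/τrot).

    Fast rotational diffusion (τrot ≪ τf) drives R to 0 regardless of the
    fundamental anisotropy R0; immobilised fluorophores (τrot ≫ τf) retain R0.
    """
    return p.r0 / (1.0 + p.tau_f / p.tau_rot)


def forward_transform(img: Image2D) -> FourierImage:
    """Unnormalised 2-D DFT (uncentred layout)."""
    return FourierImage(values=np.fft.fft2(img.values), centred=False)


def inverse_transform(f: FourierImage) -> np.ndarray:
    """Inverse DFT with 1/(mn) normalisation; real part of the round trip
    reproduces the source image to float precision."""
    values = f.values
    if f.centred:
        values = np.fft.ifftshift(values)
    return np.fft.ifft2(values)


def centre(f: FourierImage | AnisotropyImage):
    """Quadrant swap bringing DC to (⌊m/2⌋, ⌊n/2⌋)."""
    if f.centred:
        raise ValueError("image is already centred")
    out = type(f)(**{**f.__dict__, "values": np.fft.fftshift(f.values), "centred": True})
    return out


def uncentre(f: FourierImage | AnisotropyImage):
    """Inverse quadrant swap; exact inverse of :func:`centre`."""
    if not f.centred:
        raise ValueError("image is not centred")
    return type(f)(**{**f.__dict__, "values": np.fft.ifftshift(f.values), "centred": False})


def anisotropy_image_pair(
    img_h: Image2D, img_v: Image2D, cal: DetectionCalibration | None = None
) -> AnisotropyImage:
    """Fourier anisotropy image from a polarisation-resolved pair (centred).

    The designated channel is divided by the G factor first; coefficients
    where both magnitudes vanish get the neutral value 1.
    """
    if img_h.shape != img_v.shape:
        raise ValueError("channel images must share dimensions")
    h, v = img_h.values, img_v.values
    if cal is not None:
        if cal.which_divided == "horizontal":
            h = h / cal.g_factor
        else:
            v = v / cal.g_factor
    mh = np.abs(np.fft.fft2(h))
    mv = np.abs(np.fft.fft2(v))
    denom = mv + mh
    zero = denom == 0
    if np.any(zero):
        warnings.warn(f"{int(zero.sum())} coefficients with zero magnitude in both channels; set FA=1")
    ratio = np.zeros_like(denom)
    np.divide(mv - mh, denom, out=ratio, where=~zero)
    fa = 1.0 + ratio
    return AnisotropyImage(values=np.fft.fftshift(fa), centred=True, mode="pair")


def anisotropy_image_single(img: Image2D) -> AnisotropyImage:
    """Magnitude spectrum of a single image (centred).  Carries orientation
    information from both the polarisation bias and intrinsic alignment."""
    return AnisotropyImage(
        values=np.fft.fftshift(np.abs(np.fft.fft2(img.values))), centred=True, mode="single"
    )


def _ring_semiaxes(shape: tuple[int, int], radius: float) -> tuple[float, float]:
    # Elliptical rings for non-square images: ring index lives on the major
    # axis; the minor axis is scaled by the aspect ratio.
    m, n = shape
    mx = max(m, n)
    return radius * m / mx, radius * n / mx


def max_ring(shape: tuple[int, int]) -> int:
    """Largest usable ring radius (just inside the Nyquist boundary)."""
    return min(shape) // 2 - 1


def extract_ring(fa: AnisotropyImage, radius: int, n_angles: int | None = None) -> RingProfile:
    """Sample FA around the ring of the given radius by nearest-pixel lookup.

    Angles are uniform on [0, 2π); sample positions are
    (centre_row − r_row·sinθ, centre_col + r_col·cosθ) with the elliptical
    semi-axes (r_row, r_col) handling non-square images.  The default number
    of angles grows with the radius so arc spacing stays ≈1 pixel.
    """
    if not fa.centred:
        raise ValueError("ring extraction requires a centred anisotropy image")
    m, n = fa.values.shape
    if not 1 <= radius <= max_ring((m, n)):
        raise ValueError(f"radius {radius} outside [1, {max_ring((m, n))}]")
    if n_angles is None:
        n_angles = max(16, math.ceil(2 * math.pi * radius))
    thetas = np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False)
    r_row, r_col = _ring_semiaxes((m, n), radius)
    rows = np.round(m // 2 - r_row * np.sin(thetas)).astype(int)
    cols = np.round(n // 2 + r_col * np.cos(thetas)).astype(int)
    return RingProfile(radius=radius, thetas_rad=thetas, samples=fa.values[rows, cols])


def anisotropy_moments(profile: RingProfile) -> tuple[float, float]:
    """Weighted second-order circular moments of a ring profile:

        γc = Σ FA·cos2θ / Σ FA,   γs = Σ FA·sin2θ / Σ FA.

    A profile 1 + A·cos2θ has γc = A/2 (orthogonality over uniform angles).
    """
    s = np.asarray(profile.samples, dtype=float)
    total = s.sum()
    if total <= 0:
        warnings.warn("non-positive ring profile sum; moments set to 0")
        return 0.0, 0.0
    two_theta = 2.0 * profile.thetas_rad
    return float(s @ np.cos(two_theta) / total), float(s @ np.sin(two_theta) / total)


def fit_ring_series(profile: RingProfile) -> tuple[float, float, float]:
    """Least-squares fit of the truncated Fourier series
    a0/2 + a2·cos2θ + b2·sin2θ to the ring profile (computed on demand; the
    moments are the primary summary)."""
    t = profile.thetas_rad
    design = np.column_stack([0.5 * np.ones_like(t), np.cos(2 * t), np.sin(2 * t)])
    coef, *_ = np.linalg.lstsq(design, profile.samples, rcond=None)
    profile.series = (float(coef[0]), float(coef[1]), float(coef[2]))
    return profile.series


def spectrum(fa: AnisotropyImage, r_min: int = 1, r_max: int | None = None) -> AnisotropySpectrum:
    """Anisotropy moment spectra over integer ring radii [r_min, r_max].

    The DC ring is always excluded.  Pair-mode spectra of identical images are
    identically zero; noise-only pairs fluctuate about zero.
    """
    m, n = fa.values.shape
    nyq = max_ring((m, n))
    if r_max is None:
        r_max = nyq
    if not 1 <= r_min <= r_max <= nyq:
        raise ValueError(f"ring range [{r_min}, {r_max}] outside [1, {nyq}]")
    radii = np.arange(r_min, r_max + 1)
    gc = np.empty(len(radii))
    gs = np.empty(len(radii))
    ns = np.empty(len(radii), dtype=np.int64)
    for i, r in enumerate(radii):
        prof = extract_ring(fa, int(r))
        gc[i], gs[i] = anisotropy_moments(prof)
        ns[i] = len(prof.samples)
    return AnisotropySpectrum(
        frequencies=radii, gamma_c=gc, gamma_s=gs, mode=fa.mode, source_shape=(m, n), n_samples=ns
    )
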
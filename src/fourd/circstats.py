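"""Circular statistics for axial (period-180°) orientation data.

Orientations are mapped onto the circle by doubling (θ → 2θ), the standard
device for axial data: antipodal orientations 90° apart become opposite
points and cancel.  All angles are degrees on [0, 180) unless noted.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "circular_variance",
    "mean_orientation",
    "circular_std_deg",
    "rayleigh_test_axial",
    "kuiper_two_sample",
]


def _resultant(angles_deg: np.ndarray, weights: np.ndarray | None) -> tuple[complex, float]:
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        raise ValueError("empty angle set")
    if weights is None:
        w = np.ones_like(a)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must not all be zero")
    z = np.sum(w * np.exp(2j * np.deg2rad(a)))
    return z, float(total)


def circular_variance(angles_deg, weights=None) -> float:
    """V = 1 − |Σ w·exp(2iθ)| / Σw; 1 for perfect isotropy, 0 for a single
    orientation."""
    z, total = _resultant(np.asarray(angles_deg), weights)
    return float(1.0 - abs(z) / total)


def mean_orientation(angles_deg, weights=None, frame_offset_deg: float = 0.0) -> float:
    """Weighted axial mean ½·arg(Σ w·exp(2iθ)) on [0, 180), optionally
    shifted into another reporting frame (offset 90° gives the frame whose
    zero is perpendicular to ours).  Returns NaN when the resultant vanishes
    (mean undefined)."""
    z, total = _resultant(np.asarray(angles_deg), weights)
    if abs(z) / total < 1e-12:
        return float("nan")
    mean = math.degrees(0.5 * math.atan2(z.imag, z.real)) % 180.0
    return (mean + frame_offset_deg) % 180.0


def circular_std_deg(angles_deg, weights=None) -> float:
    """Axial circular standard deviation, √(−2·ln R̄)/2 in degrees."""
    z, total = _resultant(np.asarray(angles_deg), weights)
    rbar = min(abs(z) / total, 1.0)
    if rbar <= 0:
        return float("inf")
    return math.degrees(0.5 * math.sqrt(-2.0 * math.log(rbar)))


def rayleigh_test_axial(angles_deg) -> tuple[float, float]:
    """Rayleigh test for uniformity of orientations (on doubled angles).

    Returns (z, p) with z = n·R̄² and the standard finite-n corrected
    p-value; small p rejects uniformity (a dominant orientation exists).
    """
    a = np.asarray(angles_deg, dtype=float)
    n = a.size
    if n < 2:
        raise ValueError("need at least two angles")
    rbar = abs(np.mean(np.exp(2j * np.deg2rad(a))))
    z = n * rbar**2
    p = math.exp(-z) * (1 + (2 * z - z**2) / (4 * n) - (24 * z - 132 * z**2 + 76 * z**3 - 9 * z**4) / (288 * n**2))
    return float(z), float(min(max(p, 0.0), 1.0))


def _kuiper_fpp(v: float, ne: float) -> float:
    # Stephens (1970) asymptotic tail probability for the Kuiper statistic.
    lam = (math.sqrt(ne) + 0.155 + 0.24 / math.sqrt(ne)) * v
    if lam < 0.4:
        return 1.0
    p = 0.0
    for j in range(1, 101):
        term = 2.0 * (4.0 * j**2 * lam**2 - 1.0) * math.exp(-2.0 * j**2 * lam**2)
        p += term
        if abs(term) < 1e-12:
            break
    return float(min(max(p, 0.0), 1.0))


def kuiper_two_sample(angles_a_deg, angles_b_deg) -> tuple[float, float]:
    """Two-sample Kuiper test on orientation samples (doubled angles).

    Kuiper's V = D⁺ + D⁻ is invariant to the choice of circular origin,
    making it the appropriate two-sample test for angle distributions.
    Returns (V, p); small p means the two orientation distributions differ.
    """
    a = np.sort(np.deg2rad(np.asarray(angles_a_deg, dtype=float) % 180.0) * 2.0)
    b = np.sort(np.deg2rad(np.asarray(angles_b_deg, dtype=float) % 180.0) * 2.0)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("need at least two angles in each sample")
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / na
    cdf_b = np.searchsorted(b, grid, side="right") / nb
    diff = cdf_a - cdf_b
    v = float(diff.max() - diff.min())
    ne = na * nb / (na + nb)
    return v, _kuiper_fpp(v, ne)
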
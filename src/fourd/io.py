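"""TIFF / CSV / JSON input and output."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .ring import AnisotropySpectrum, Image2D

__all__ = [
    "SchemaError",
    "read_image",
    "write_image",
    "write_spectrum",
    "read_spectrum",
    "write_truth",
    "write_maps",
    "write_histogram",
]

_SPECTRUM_COLUMNS = ["ring_index", "freq_per_pixel", "gamma_c", "gamma_s", "n_samples"]


class SchemaError(ValueError):
    """A file does not match the expected tabular schema."""


def read_image(path: str | Path) -> Image2D:
    """Read a single-plane greyscale TIFF (8/16-bit unsigned or float).

    Multi-page and multi-channel (RGB) files are rejected: extract the
    channel of interest first.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        if len(tf.pages) > 1:
            raise ValueError(f"{path} is a multi-page TIFF; supply a single plane")
        arr = tf.asarray()
        pixel_size = None
        page = tf.pages[0]
        res = page.tags.get("XResolution")
        if res is not None and res.value[0]:
            num, den = res.value
            if num:
                pixel_size = den / num  # units per pixel as stored
    if arr.ndim == 3:
        raise ValueError(
            f"{path} has {arr.shape[-1]} channels; extract a single greyscale channel first"
        )
    if arr.ndim != 2:
        raise ValueError(f"{path} is not a 2-D image (shape {arr.shape})")
    return Image2D(values=arr.astype(np.float64), pixel_size=pixel_size, metadata={"path": str(path)})


def write_image(path: str | Path, img: Image2D | np.ndarray, dtype: str = "float32") -> None:
    """Write a TIFF as 32-bit float (values preserved, including negatives)
    or 16-bit unsigned (clipped to [0, 65535] and rounded)."""
    values = img.values if isinstance(img, Image2D) else np.asarray(img)
    if dtype == "float32":
        out = values.astype(np.float32)
    elif dtype == "uint16":
        out = np.clip(np.round(values), 0, 65535).astype(np.uint16)
    else:
        raise ValueError("dtype must be 'float32' or 'uint16'")
    tifffile.imwrite(Path(path), out)


def write_spectrum(path: str | Path, spec: AnisotropySpectrum, g_factor: float | None = None) -> None:
    m, n = spec.source_shape
    header = [
        f"# mode: {spec.mode}",
        f"# source_shape: {m} {n}",
        f"# g_factor: {'' if g_factor is None else g_factor}",
    ]
    n_samples = (
        spec.n_samples if spec.n_samples is not None else np.zeros(len(spec.frequencies), dtype=int)
    )
    df = pd.DataFrame(
        {
            "ring_index": spec.frequencies,
            "freq_per_pixel": spec.frequencies / max(m, n),
            "gamma_c": spec.gamma_c,
            "gamma_s": spec.gamma_s,
            "n_samples": n_samples,
        }
    )
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_spectrum(path: str | Path) -> AnisotropySpectrum:
    path = Path(path)
    mode, shape = "single", (0, 0)
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition(":")
            key, value = key.strip(), value.strip()
            if key == "mode":
                mode = value
            elif key == "source_shape":
                parts = value.split()
                shape = (int(parts[0]), int(parts[1]))
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty spectrum file") from exc
    missing = [c for c in _SPECTRUM_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise SchemaError(f"{path}: spectrum has no rows")
    return AnisotropySpectrum(
        frequencies=df["ring_index"].to_numpy(),
        gamma_c=df["gamma_c"].to_numpy(),
        gamma_s=df["gamma_s"].to_numpy(),
        mode=mode,
        source_shape=shape,
        n_samples=df["n_samples"].to_numpy(),
    )


def write_truth(path: str | Path, field, settings=None) -> None:
    """Ground-truth CSV sidecar for a simulated fibre field."""
    from .simulate import polarisation_factor

    rows = []
    width = field.recipe.canvas_px[1]
    for i, f in enumerate(field.fibres):
        mult = 1.0
        if settings is not None:
            col_frac = f.origin[1] / width if settings.gradient else None
            mult = float(polarisation_factor(f.angle_deg, settings, col_frac))
        rows.append(
            {
                "fibre_id": i,
                "angle_deg": f.angle_deg,
                "length_px": f.length_px,
                "row": f.origin[0],
                "col": f.origin[1],
                "multiplier": mult,
            }
        )
    pd.DataFrame(rows, columns=["fibre_id", "angle_deg", "length_px", "row", "col", "multiplier"]).to_csv(
        path, index=False
    )


def write_maps(outdir: str | Path, maps) -> None:
    """Angle/eccentricity maps as float TIFFs plus a tidy CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_image(outdir / "angle_map.tif", maps.angle_map.astype(np.float32))
    write_image(outdir / "eccentricity_map.tif", maps.eccentricity_map.astype(np.float32))
    nr, nc = maps.angle_map.shape
    rows, cols = np.meshgrid(range(nr), range(nc), indexing="ij")
    pd.DataFrame(
        {
            "window_row": rows.ravel(),
            "window_col": cols.ravel(),
            "angle_deg": maps.angle_map.ravel(),
            "eccentricity": maps.eccentricity_map.ravel(),
        }
    ).to_csv(outdir / "alignment.csv", index=False)


def write_histogram(path: str | Path, angles_deg: np.ndarray, weights: np.ndarray) -> None:
    pd.DataFrame({"angle_deg": angles_deg, "weight": weights}).to_csv(path, index=False)


def write_json(path: str | Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
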
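"""Rendering CWT coefficient matrices as fixed-size color scalogram images.

A scalogram is rendered directly from the coefficient matrix — per-image
min-max normalization, bilinear resize to 224x224, then a perceptually
ordered dark-blue-to-bright-yellow colormap (viridis) — rather than through
a plotting canvas, so images are bit-reproducible and margin-free.  Row 0
is the smallest scale (highest pseudo-frequency); time runs left to right.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from matplotlib import colormaps
from PIL import Image

from .wavelets import CWTResult

IMAGE_SIZE = 224
DEFAULT_COLORMAP = "viridis"


@dataclass
class ScalogramImage:
    """224x224x3 8-bit color image plus provenance metadata."""

    pixels: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.shape != (IMAGE_SIZE, IMAGE_SIZE, 3):
            raise ValueError(
                f"pixels must be ({IMAGE_SIZE}, {IMAGE_SIZE}, 3), "
                f"got {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be uint8")


def coeffs_to_matrix(result: CWTResult, mode: str = "auto") -> np.ndarray:
    """Reduce CWT coefficients to a real matrix.

    ``magnitude`` takes |W|; ``real`` takes Re(W); ``auto`` uses magnitude
    for complex wavelets and the real part for real ones.
    """
    if mode == "auto":
        mode = "magnitude" if result.spec.is_complex else "real"
    if mode == "magnitude":
        return np.abs(result.coeffs)
    if mode == "real":
        return np.real(result.coeffs)
    raise ValueError(f"mode must be 'magnitude', 'real' or 'auto', got {mode!r}")


def _normalize(matrix: np.ndarray) -> tuple[np.ndarray, float, float]:
    lo, hi = float(matrix.min()), float(matrix.max())
    if hi > lo:
        return (matrix - lo) / (hi - lo), lo, hi
    # constant matrix maps to the colormap midpoint
    return np.full_like(matrix, 0.5, dtype=float), lo, hi


def render(
    matrix: np.ndarray,
    colormap: str = DEFAULT_COLORMAP,
    size: int = IMAGE_SIZE,
    meta: dict | None = None,
) -> ScalogramImage:
    """Render a real coefficient matrix as a ``size`` x ``size`` color image."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        raise ValueError("matrix is empty")
    if not np.all(np.isfinite(matrix)):
        bad = np.argwhere(~np.isfinite(matrix))[0]
        raise ValueError(f"non-finite coefficient at (scale={bad[0]}, t={bad[1]})")
    norm, lo, hi = _normalize(matrix)
    resized = np.asarray(
        Image.fromarray(norm.astype(np.float32), mode="F").resize(
            (size, size), resample=Image.BILINEAR
        ),
        dtype=float,
    )
    resized = np.clip(resized, 0.0, 1.0)
    rgba = colormaps[colormap](resized)  # (H, W, 4) floats in [0, 1]
    pixels = (rgba[..., :3] * 255.0).round().astype(np.uint8)
    info = {"colormap": colormap, "norm_min": lo, "norm_max": hi,
            "orientation": "row0=smallest_scale,time_left_to_right"}
    if meta:
        info.update(meta)
    return ScalogramImage(pixels=pixels, meta=info)


def render_cwt(
    result: CWTResult, mode: str = "auto", colormap: str = DEFAULT_COLORMAP
) -> ScalogramImage:
    """CWT result -> matrix -> image, recording wavelet provenance."""
    matrix = coeffs_to_matrix(result, mode)
    meta = {
        "wavelet": result.spec.name,
        "mode": "magnitude" if (mode == "auto" and result.spec.is_complex) else (
            "real" if mode == "auto" else mode),
        "n_scales": int(result.scales.size),
        "scale_min": float(result.scales[0]),
        "scale_max": float(result.scales[-1]),
        "fs": result.fs,
    }
    return render(matrix, colormap=colormap, meta=meta)


def render_raw_segment(segment: np.ndarray, size: int = IMAGE_SIZE) -> ScalogramImage:
    """No-CWT baseline image: normalized 1-D segment tiled into a gray image.

    The segment is min-max normalized, linearly resampled to ``size``
    columns, and repeated across all rows; the three channels are equal.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.size < 2:
        raise ValueError("segment must have at least 2 samples")
    norm, _, _ = _normalize(segment)
    xs = np.linspace(0, segment.size - 1, size)
    row = np.interp(xs, np.arange(segment.size), norm)
    gray = (np.tile(row, (size, 1)) * 255.0).round().astype(np.uint8)
    pixels = np.repeat(gray[:, :, None], 3, axis=2)
    return ScalogramImage(pixels=pixels, meta={"wavelet": "none", "mode": "raw"})


def save_image(img: ScalogramImage, path: str | Path) -> None:
    """Lossless PNG write plus a JSON metadata sidecar."""
    path = Path(path)
    Image.fromarray(img.pixels, mode="RGB").save(path, format="PNG")
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(img.meta, indent=2))


def load_image(path: str | Path) -> ScalogramImage:
    """Read back a PNG + sidecar written by :func:`save_image`."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            pixels = np.asarray(im.convert("RGB"), dtype=np.uint8)
    except OSError as exc:
        raise OSError(f"cannot read scalogram image {path}: {exc}") from exc
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return ScalogramImage(pixels=pixels, meta=meta)
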
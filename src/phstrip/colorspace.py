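"""Conversions between 8-bit sRGB pixel values and CIE 1976 u'v' chromaticity.

All color fitting and matching in this package happens in the u'v' (UCS)
chromaticity plane, which is intensity-invariant: scaling a color's linear
RGB by any positive factor leaves (u', v') unchanged.  Input images are
assumed to be sRGB-encoded (IEC 61966-2-1, D65 white), the default output
of smartphone cameras.

Patch colors are averaged in *linear* RGB before converting to u'v'
(chromaticity is a ratio, so averaging after conversion is biased); the
alternative is available via ``mean_patch_uv(..., average="uv")``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2xyz

__all__ = [
    "RGBColor",
    "UVColor",
    "D65_UV",
    "rgb_to_uv",
    "rgb_array_to_uv",
    "uv_to_rgb_display",
    "srgb_to_linear",
    "linear_to_srgb",
    "linear_rgb_to_uv",
    "relative_luminance",
    "mean_patch_uv",
]


@dataclass(frozen=True)
class RGBColor:
    """An 8-bit sRGB color; each channel in [0, 255]."""

    r: int
    g: int
    b: int

    def __post_init__(self) -> None:
        for name in ("r", "g", "b"):
            val = getattr(self, name)
            if not 0 <= val <= 255:
                raise ValueError(f"channel {name}={val} outside [0, 255]")

    def as_array(self) -> np.ndarray:
        return np.array([self.r, self.g, self.b], dtype=np.uint8)


@dataclass(frozen=True)
class UVColor:
    """A CIE 1976 u'v' chromaticity point."""

    u: float
    v: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.u) and np.isfinite(self.v)):
            raise ValueError(f"non-finite chromaticity ({self.u}, {self.v})")

    def as_array(self) -> np.ndarray:
        return np.array([self.u, self.v], dtype=float)


def _d65_uv() -> "UVColor":
    xyz = rgb2xyz(np.ones((1, 1, 3)))[0, 0]
    u, v = _xyz_to_uv(xyz[None, :])[0]
    return UVColor(float(u), float(v))


def srgb_to_linear(srgb: np.ndarray) -> np.ndarray:
    """Decode sRGB values in [0, 1] to linear RGB (IEC 61966-2-1)."""
    srgb = np.asarray(srgb, dtype=float)
    low = srgb <= 0.04045
    return np.where(low, srgb / 12.92, ((srgb + 0.055) / 1.055) ** 2.4)


def linear_to_srgb(linear: np.ndarray) -> np.ndarray:
    """Encode linear RGB in [0, 1] to sRGB values."""
    linear = np.asarray(linear, dtype=float)
    low = linear <= 0.0031308
    return np.where(low, 12.92 * linear, 1.055 * np.clip(linear, 0, None) ** (1 / 2.4) - 0.055)


# sRGB D65 matrix taken from skimage so both pathways agree bit-for-bit.
# The unit pixels pass through the gamma decode unchanged, so the converted
# rows are exactly the matrix columns.
_RGB2XYZ = rgb2xyz(np.eye(3).reshape(1, 3, 3))[0].T


def _xyz_to_uv(xyz: np.ndarray) -> np.ndarray:
    xyz = np.asarray(xyz, dtype=float)
    denom = xyz[..., 0] + 15.0 * xyz[..., 1] + 3.0 * xyz[..., 2]
    degenerate = denom <= 0
    if np.any(degenerate):
        warnings.warn(
            "degenerate color with X+15Y+3Z = 0 (pure black); "
            "returning D65 white point chromaticity",
            RuntimeWarning,
            stacklevel=2,
        )
        denom = np.where(degenerate, 1.0, denom)
    u = 4.0 * xyz[..., 0] / denom
    v = 9.0 * xyz[..., 1] / denom
    if np.any(degenerate):
        # D65 white of the sRGB system.
        wxyz = _RGB2XYZ @ np.ones(3)
        wd = wxyz[0] + 15.0 * wxyz[1] + 3.0 * wxyz[2]
        u = np.where(degenerate, 4.0 * wxyz[0] / wd, u)
        v = np.where(degenerate, 9.0 * wxyz[1] / wd, v)
    return np.stack([u, v], axis=-1)


def linear_rgb_to_uv(linear: np.ndarray) -> np.ndarray:
    """Map linear RGB (..., 3) in [0, 1] to u'v' chromaticity (..., 2)."""
    linear = np.asarray(linear, dtype=float)
    xyz = linear @ _RGB2XYZ.T
    return _xyz_to_uv(xyz)


def rgb_array_to_uv(rgb: np.ndarray) -> np.ndarray:
    """Map 8-bit sRGB values with shape (..., 3) to u'v' with shape (..., 2)."""
    rgb = np.asarray(rgb)
    if rgb.shape[-1] != 3:
        raise ValueError("expected trailing axis of size 3")
    return linear_rgb_to_uv(srgb_to_linear(rgb.astype(float) / 255.0))


def rgb_to_uv(c: RGBColor) -> UVColor:
    """Convert one 8-bit sRGB color to CIE 1976 u'v' chromaticity.

    Pure black (the only input with X + 15Y + 3Z = 0) maps to the D65 white
    point with a warning so downstream fits never see non-finite values.
    """
    uv = rgb_array_to_uv(c.as_array()[None, :])[0]
    return UVColor(float(uv[0]), float(uv[1]))


def relative_luminance(linear: np.ndarray) -> np.ndarray:
    """Relative luminance Y of linear RGB values (the XYZ Y row)."""
    return np.asarray(linear, dtype=float) @ _RGB2XYZ[1]


def uv_to_rgb_display(c: UVColor, luminance_y: float = 0.5) -> RGBColor:
    """Render a chromaticity at a fixed luminance Y in (0, 1] as 8-bit sRGB.

    Out-of-gamut channels are clipped to [0, 255]; no error is raised.
    """
    if not 0 < luminance_y <= 1:
        raise ValueError("luminance_y must be in (0, 1]")
    rgb = uv_array_to_rgb_display(np.array([[c.u, c.v]]), luminance_y)[0]
    return RGBColor(int(rgb[0]), int(rgb[1]), int(rgb[2]))


def uv_array_to_rgb_display(uv: np.ndarray, luminance_y) -> np.ndarray:
    """Vectorized form of :func:`uv_to_rgb_display`; returns uint8 (..., 3)."""
    uv = np.asarray(uv, dtype=float)
    y = np.broadcast_to(np.asarray(luminance_y, dtype=float), uv.shape[:-1])
    u, v = uv[..., 0], uv[..., 1]
    if np.any(v <= 0):
        raise ValueError("v' must be positive to reconstruct XYZ")
    x = y * 9.0 * u / (4.0 * v)
    z = y * (12.0 - 3.0 * u - 20.0 * v) / (4.0 * v)
    xyz = np.stack([x, y, z], axis=-1)
    linear = xyz @ np.linalg.inv(_RGB2XYZ).T
    srgb = linear_to_srgb(np.clip(linear, 0.0, 1.0))
    return np.clip(np.round(srgb * 255.0), 0, 255).astype(np.uint8)


def mean_patch_uv(
    image: np.ndarray,
    center: tuple[float, float],
    half_window: int,
    average: str = "linear-rgb",
) -> UVColor:
    """Average a square pixel window around ``center`` (x, y) and convert to u'v'.

    ``average="linear-rgb"`` (default) averages in linear RGB before the
    chromaticity conversion; ``average="uv"`` converts each pixel first and
    averages chromaticities.  Windows crossing the image boundary are clipped
    with a warning.
    """
    if half_window < 0:
        raise ValueError("half_window must be >= 0")
    h, w = image.shape[:2]
    cx, cy = int(round(center[0])), int(round(center[1]))
    x0, x1 = cx - half_window, cx + half_window + 1
    y0, y1 = cy - half_window, cy + half_window + 1
    if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
        warnings.warn("sampling window clipped at image boundary", RuntimeWarning, stacklevel=2)
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1, w), min(y1, h)
    if x1 <= x0 or y1 <= y0:
        raise ValueError("sampling window entirely outside the image")
    patch = image[y0:y1, x0:x1].astype(float) / 255.0
    if average == "linear-rgb":
        mean_linear = srgb_to_linear(patch).reshape(-1, 3).mean(axis=0)
        uv = linear_rgb_to_uv(mean_linear[None, :])[0]
    elif average == "uv":
        uv = linear_rgb_to_uv(srgb_to_linear(patch)).reshape(-1, 2).mean(axis=0)
    else:
        raise ValueError(f"unknown averaging mode {average!r}")
    return UVColor(float(uv[0]), float(uv[1]))


D65_UV = _d65_uv()
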
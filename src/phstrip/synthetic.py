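"""Render ground-truth light-box scenes for testing without hardware.

A scene holds two reference rectangles (6x18 grids of distinct colors, long
side horizontal, aspect ~3.8) near the top and bottom of the frame and a
central vertical strip of four square patches whose colors follow a smooth
per-patch color-vs-pH model.  A camera model optionally applies a
polynomial u'v' color distortion (the same family the fitter uses, so
"can we invert what we model" is separable from out-of-family robustness),
a brightness gain, an affine geometry change, and additive pixel noise.
All randomness is seeded; renders are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.stats import qmc
from skimage.transform import AffineTransform, warp

from .adaptation import PolyColorModel
from .colorspace import (
    linear_rgb_to_uv,
    relative_luminance,
    srgb_to_linear,
    uv_array_to_rgb_display,
)

__all__ = [
    "SceneGeometry",
    "StripModel",
    "Palette",
    "CameraModel",
    "GroundTruth",
    "default_palette",
    "random_mild_distortion",
    "render_chart_capture",
    "render_measurement_capture",
]

ROWS_PER_REF = 6
COLS = 18
N_PATCHES = 4


@dataclass(frozen=True)
class SceneGeometry:
    """Nominal pixel layout before any camera geometry is applied."""

    width: int = 960
    height: int = 720
    ref_origin_x: int = 264
    upper_ref_origin_y: int = 93
    lower_ref_origin_y: int = 513
    cell_w: int = 24
    cell_h: int = 19
    patch_size: int = 32
    patch_center_x: int = 480
    patch_centers_y: tuple[int, ...] = (288, 336, 384, 432)
    border: int = 4
    background: tuple[int, int, int] = (210, 210, 210)

    @property
    def ref_width(self) -> int:
        return self.cell_w * COLS

    @property
    def ref_height(self) -> int:
        return self.cell_h * ROWS_PER_REF

    def reference_centers(self) -> np.ndarray:
        """(12, 18, 2) nominal cell centers, upper rows then lower rows."""
        xs = self.ref_origin_x + self.cell_w * (np.arange(COLS) + 0.5)
        out = np.empty((2 * ROWS_PER_REF, COLS, 2))
        for half, oy in enumerate((self.upper_ref_origin_y, self.lower_ref_origin_y)):
            ys = oy + self.cell_h * (np.arange(ROWS_PER_REF) + 0.5)
            for i, y in enumerate(ys):
                out[half * ROWS_PER_REF + i, :, 0] = xs
                out[half * ROWS_PER_REF + i, :, 1] = y
        return out

    def target_centers(self) -> np.ndarray:
        return np.array(
            [[self.patch_center_x, y] for y in self.patch_centers_y], dtype=float
        )


class StripModel:
    """Smooth per-patch color as a function of pH.

    Piecewise-cubic (natural spline) through anchor sRGB colors given at the
    integer pH values 0..14; continuous in p and clipped to [0, 1].
    """

    def __init__(self, anchors: np.ndarray):
        anchors = np.asarray(anchors, dtype=float)
        if anchors.shape != (N_PATCHES, 15, 3):
            raise ValueError(f"expected anchors of shape (4, 15, 3), got {anchors.shape}")
        if anchors.min() < 0 or anchors.max() > 1:
            raise ValueError("anchor colors must lie in [0, 1]")
        self.anchors = anchors
        x = np.arange(15.0)
        self._splines = [
            [CubicSpline(x, anchors[k, :, ch], bc_type="natural") for ch in range(3)]
            for k in range(N_PATCHES)
        ]

    def srgb(self, p: float) -> np.ndarray:
        """(4, 3) sRGB float colors of the strip at pH ``p``."""
        if not 0 <= p <= 14:
            raise ValueError(f"pH {p} outside [0, 14]")
        out = np.array(
            [[self._splines[k][ch](p) for ch in range(3)] for k in range(N_PATCHES)]
        )
        return np.clip(out, 0.0, 1.0)

    def uv(self, p: float) -> np.ndarray:
        """(4, 2) u'v' of the (unquantized) strip colors at pH ``p``."""
        return linear_rgb_to_uv(srgb_to_linear(self.srgb(p)))


@dataclass(frozen=True)
class Palette:
    """Master reference colors plus the strip color-vs-pH model."""

    reference_colors: np.ndarray  # (12, 18, 3) uint8
    strip_model: StripModel

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference_colors)
        if ref.shape != (2 * ROWS_PER_REF, COLS, 3):
            raise ValueError("reference_colors must have shape (12, 18, 3)")
        object.__setattr__(self, "reference_colors", ref.astype(np.uint8))

    def reference_uv(self) -> np.ndarray:
        return linear_rgb_to_uv(srgb_to_linear(self.reference_colors.astype(float) / 255.0))

    def min_pairwise_uv_distance(self) -> float:
        uv = self.reference_uv().reshape(-1, 2)
        diff = uv[:, None, :] - uv[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        return float(dist.min())


@dataclass(frozen=True)
class CameraModel:
    """Per-capture camera behavior: color distortion, gain, geometry, noise."""

    color_distortion: PolyColorModel | None = None
    brightness_gain: float = 1.0
    noise_sigma: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)
    rotation_deg: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.brightness_gain <= 0:
            raise ValueError("brightness_gain must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")

    @property
    def is_color_identity(self) -> bool:
        return self.color_distortion is None and self.brightness_gain == 1.0


@dataclass(frozen=True)
class GroundTruth:
    """Oracle record accompanying one rendered scene."""

    ph: float | None
    reference_positions: np.ndarray  # (12, 18, 2) post-geometry
    target_positions: np.ndarray  # (4, 2)
    reference_uv_true: np.ndarray  # (12, 18, 2) pre-distortion
    reference_uv_image: np.ndarray  # (12, 18, 2) as drawn (post-distortion, quantized)
    target_uv_true: np.ndarray  # (4, 2)
    target_uv_image: np.ndarray  # (4, 2)
    reference_rgb_drawn: np.ndarray  # (12, 18, 3) uint8
    target_rgb_drawn: np.ndarray  # (4, 3) uint8

    def region_centers(self) -> np.ndarray:
        """(6, 2): centers of upper ref, lower ref, and the 4 patches."""
        upper = self.reference_positions[:ROWS_PER_REF].reshape(-1, 2).mean(axis=0)
        lower = self.reference_positions[ROWS_PER_REF:].reshape(-1, 2).mean(axis=0)
        return np.vstack([upper, lower, self.target_positions])

    def to_dict(self) -> dict:
        return {
            "ph": self.ph,
            "reference_positions": self.reference_positions.tolist(),
            "target_positions": self.target_positions.tolist(),
            "reference_uv_true": self.reference_uv_true.tolist(),
            "reference_uv_image": self.reference_uv_image.tolist(),
            "target_uv_true": self.target_uv_true.tolist(),
            "target_uv_image": self.target_uv_image.tolist(),
            "reference_rgb_drawn": self.reference_rgb_drawn.tolist(),
            "target_rgb_drawn": self.target_rgb_drawn.tolist(),
        }


def _default_strip_anchors() -> np.ndarray:
    t = np.arange(15.0) / 14.0
    s = np.sin(np.pi * t)
    anchors = np.empty((N_PATCHES, 15, 3))
    anchors[0] = np.stack([0.75 - 0.50 * t, 0.25 + 0.55 * t, 0.28 + 0.10 * s], axis=1)
    anchors[1] = np.stack([0.80 - 0.20 * t, 0.70 - 0.45 * t, 0.25 + 0.55 * t], axis=1)
    anchors[2] = np.stack([0.30 + 0.50 * t, 0.62 - 0.20 * t - 0.10 * s, 0.72 - 0.45 * t], axis=1)
    anchors[3] = np.stack([0.35 + 0.45 * t, 0.28 + 0.10 * t + 0.08 * s, 0.32 + 0.45 * t], axis=1)
    return anchors


def default_palette(seed: int = 0, min_uv_distance: float = 0.011) -> Palette:
    """Deterministic palette: low-discrepancy reference colors, smooth strip.

    Reference colors are drawn from a scrambled Halton sequence over a
    moderately saturated sRGB box and greedily thinned so every pair is at
    least ``min_uv_distance`` apart in u'v' (well-conditioned fits need
    spread chromaticities).
    """
    sampler = qmc.Halton(d=3, scramble=True, seed=seed)
    accepted_rgb: list[np.ndarray] = []
    accepted_uv: list[np.ndarray] = []
    n_needed = 2 * ROWS_PER_REF * COLS
    while len(accepted_rgb) < n_needed:
        batch = sampler.random(512)
        srgb = 0.25 + 0.67 * batch  # keep clear of gamut edges and of the black borders
        uv = linear_rgb_to_uv(srgb_to_linear(srgb))
        for c_srgb, c_uv in zip(srgb, uv):
            if accepted_uv:
                dmin = np.sqrt(((np.array(accepted_uv) - c_uv) ** 2).sum(1)).min()
                if dmin <= min_uv_distance:
                    continue
            quant = np.round(c_srgb * 255.0)
            quant_uv = linear_rgb_to_uv(srgb_to_linear(quant[None] / 255.0))[0]
            if accepted_uv:
                dmin = np.sqrt(((np.array(accepted_uv) - quant_uv) ** 2).sum(1)).min()
                if dmin <= min_uv_distance:
                    continue
            accepted_rgb.append(quant.astype(np.uint8))
            accepted_uv.append(quant_uv)
            if len(accepted_rgb) == n_needed:
                break
    ref = np.array(accepted_rgb).reshape(2 * ROWS_PER_REF, COLS, 3)
    return Palette(reference_colors=ref, strip_model=StripModel(_default_strip_anchors()))


def random_mild_distortion(rng: np.random.Generator, strength: float = 0.05) -> PolyColorModel:
    """A random third-order u'v' distortion near identity.

    The identity (linear) coefficients are perturbed multiplicatively by up
    to ``strength``; the remaining coefficients get additive perturbations
    scaled so each monomial contributes a comparable, small chromaticity
    shift over the working u'v' range.
    """
    # additive scales per basis term [u, v, 1, u2, v2, uv, u3, v3, u2v, uv2]
    scales = np.array([0.15, 0.15, 0.03, 0.15, 0.15, 0.15, 0.10, 0.10, 0.10, 0.10])
    model = PolyColorModel.identity()
    a_u = model.a_u + rng.uniform(-strength, strength, 10) * scales
    a_v = model.a_v + rng.uniform(-strength, strength, 10) * scales
    a_u[0] = 1.0 + rng.uniform(-strength, strength)
    a_v[1] = 1.0 + rng.uniform(-strength, strength)
    return PolyColorModel(a_u, a_v)


def _camera_color(srgb: np.ndarray, camera: CameraModel) -> np.ndarray:
    """Drawn uint8 colors for (n, 3) float sRGB inputs under the camera model."""
    srgb = np.asarray(srgb, dtype=float)
    if camera.is_color_identity:
        return np.clip(np.round(srgb * 255.0), 0, 255).astype(np.uint8)
    linear = srgb_to_linear(srgb)
    y = np.clip(relative_luminance(linear) * camera.brightness_gain, 1e-4, 1.0)
    uv = linear_rgb_to_uv(linear)
    if camera.color_distortion is not None:
        uv = camera.color_distortion.apply_array(uv)
    return uv_array_to_rgb_display(uv, y)


def _fill_rect(img: np.ndarray, x0: int, y0: int, x1: int, y1: int, color) -> None:
    img[y0:y1, x0:x1] = color


def _draw_reference(img, geom: SceneGeometry, origin_y: int, colors_u8: np.ndarray) -> None:
    x0, b = geom.ref_origin_x, geom.border
    for i in range(ROWS_PER_REF):
        for j in range(COLS):
            _fill_rect(
                img,
                x0 + j * geom.cell_w,
                origin_y + i * geom.cell_h,
                x0 + (j + 1) * geom.cell_w,
                origin_y + (i + 1) * geom.cell_h,
                colors_u8[i, j],
            )
    # black grid lines: internal lines centered on the cell boundaries, the
    # outer frame fully inside the rectangle so the detected outer edge
    # coincides with the cell-grid extent
    x1 = x0 + geom.ref_width
    y1 = origin_y + geom.ref_height
    for j in range(1, COLS):
        x = x0 + j * geom.cell_w
        _fill_rect(img, x - b // 2, origin_y, x + (b + 1) // 2, y1, (0, 0, 0))
    for i in range(1, ROWS_PER_REF):
        y = origin_y + i * geom.cell_h
        _fill_rect(img, x0, y - b // 2, x1, y + (b + 1) // 2, (0, 0, 0))
    _fill_rect(img, x0, origin_y, x0 + b, y1, (0, 0, 0))
    _fill_rect(img, x1 - b, origin_y, x1, y1, (0, 0, 0))
    _fill_rect(img, x0, origin_y, x1, origin_y + b, (0, 0, 0))
    _fill_rect(img, x0, y1 - b, x1, y1, (0, 0, 0))


def _geometry_transform(camera: CameraModel, geom: SceneGeometry) -> AffineTransform:
    c = np.array([geom.width, geom.height]) / 2.0
    to_origin = AffineTransform(translation=-c)
    rot_scale = AffineTransform(rotation=np.deg2rad(camera.rotation_deg), scale=camera.scale)
    back = AffineTransform(translation=c + np.asarray(camera.translation, float))
    return AffineTransform(matrix=back.params @ rot_scale.params @ to_origin.params)


def _render_scene(
    palette: Palette,
    camera: CameraModel,
    strip_srgb: np.ndarray,
    ph: float | None,
    seed: int | None,
) -> tuple[np.ndarray, GroundTruth]:
    geom = SceneGeometry()
    img = np.empty((geom.height, geom.width, 3), dtype=np.uint8)
    img[:] = _camera_color(np.asarray(geom.background, float)[None] / 255.0, camera)[0]

    ref_drawn = _camera_color(
        palette.reference_colors.reshape(-1, 3).astype(float) / 255.0, camera
    ).reshape(2 * ROWS_PER_REF, COLS, 3)
    tgt_drawn = _camera_color(strip_srgb, camera)

    _draw_reference(img, geom, geom.upper_ref_origin_y, ref_drawn[:ROWS_PER_REF])
    _draw_reference(img, geom, geom.lower_ref_origin_y, ref_drawn[ROWS_PER_REF:])
    half = geom.patch_size // 2
    b = geom.border
    for k, cy in enumerate(geom.patch_centers_y):
        x0, y0 = geom.patch_center_x - half, cy - half
        x1, y1 = x0 + geom.patch_size, y0 + geom.patch_size
        _fill_rect(img, x0 - b, y0 - b, x1 + b, y1 + b, (0, 0, 0))
        _fill_rect(img, x0, y0, x1, y1, tgt_drawn[k])

    tform = _geometry_transform(camera, SceneGeometry())
    ref_pos = geom.reference_centers()
    tgt_pos = geom.target_centers()
    identity_geom = (
        camera.rotation_deg == 0 and camera.scale == 1 and tuple(camera.translation) == (0.0, 0.0)
    )
    if not identity_geom:
        corners = np.array(
            [
                [geom.ref_origin_x - b, geom.upper_ref_origin_y - b],
                [geom.ref_origin_x + geom.ref_width + b, geom.upper_ref_origin_y - b],
                [geom.ref_origin_x - b, geom.lower_ref_origin_y + geom.ref_height + b],
                [geom.ref_origin_x + geom.ref_width + b, geom.lower_ref_origin_y + geom.ref_height + b],
            ],
            dtype=float,
        )
        moved = tform(corners)
        if (
            moved.min() < 0
            or moved[:, 0].max() > geom.width - 1
            or moved[:, 1].max() > geom.height - 1
        ):
            raise ValueError("camera geometry pushes the reference regions off-image")
        img = warp(img, tform.inverse, order=0, mode="edge", preserve_range=True).astype(np.uint8)
        ref_pos = tform(ref_pos.reshape(-1, 2)).reshape(ref_pos.shape)
        tgt_pos = tform(tgt_pos)

    if camera.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        noisy = img.astype(float) + rng.normal(0.0, camera.noise_sigma, img.shape)
        img = np.clip(np.round(noisy), 0, 255).astype(np.uint8)

    strip_quant = np.clip(np.round(strip_srgb * 255.0), 0, 255).astype(np.uint8)
    truth = GroundTruth(
        ph=ph,
        reference_positions=ref_pos,
        target_positions=tgt_pos,
        reference_uv_true=palette.reference_uv(),
        reference_uv_image=linear_rgb_to_uv(srgb_to_linear(ref_drawn.astype(float) / 255.0)),
        target_uv_true=linear_rgb_to_uv(srgb_to_linear(strip_quant.astype(float) / 255.0)),
        target_uv_image=linear_rgb_to_uv(srgb_to_linear(tgt_drawn.astype(float) / 255.0)),
        reference_rgb_drawn=ref_drawn,
        target_rgb_drawn=tgt_drawn,
    )
    return img, truth


def render_chart_capture(
    palette: Palette, camera: CameraModel, ph_index: int, seed: int | None = 0
) -> tuple[np.ndarray, GroundTruth]:
    """Render one comparison-chart capture at an integer pH index."""
    if ph_index not in range(15):
        raise ValueError(f"ph_index {ph_index} outside 0..14")
    return _render_scene(palette, camera, palette.strip_model.srgb(float(ph_index)),
                         float(ph_index), seed)


def render_measurement_capture(
    palette: Palette, camera: CameraModel, true_ph: float, seed: int | None = 0
) -> tuple[np.ndarray, GroundTruth]:
    """Render one measurement capture with the strip at a continuous pH."""
    if not 0 <= true_ph <= 14:
        raise ValueError(f"true_ph {true_ph} outside [0, 14]")
    return _render_scene(palette, camera, palette.strip_model.srgb(float(true_ph)),
                         float(true_ph), seed)
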
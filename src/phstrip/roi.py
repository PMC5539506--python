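"""Automatic color retrieval: locate reference rectangles and strip patches.

Six steps: median-filter simplification, Canny edge detection with
morphological closing, initial contour extraction (rectangular, convex,
non-tiny), contour labeling (long reference rectangles away from the
center line vs. square target patches near it), principal-axis sampling
grid placement, and windowed color retrieval.

Conventions used throughout:

* Pixel coordinates are 0-based ``(x right, y down)``; cell centers sit at
  half-integer positions.
* The "center line" is the image's horizontal midline: the strip lies
  between the upper and lower reference papers, so target contours sit near
  mid-height and reference contours far from it.  The band half-width is
  ``center_band`` times the image height.
* Reference-grid columns are anchored at the end of the major axis nearer
  the image's left edge; rows run top to bottom.  Calibration and
  measurement captures must share this orientation.
* Target patches are labeled k = 1..4 from top to bottom along the strip
  axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from shapely.geometry import LineString, Point, Polygon
from skimage import feature, measure

from .calibration import GRID_COLS, GRID_ROWS, ReferenceGrid, TargetPatchColors
from .colorspace import mean_patch_uv

__all__ = [
    "DetectionConfig",
    "DetectionError",
    "Contour",
    "SceneLayout",
    "simplify",
    "detect_edges",
    "extract_initial_contours",
    "label_contours",
    "place_sampling_grid",
    "retrieve_colors",
    "detect_scene",
]

HALF_ROWS = GRID_ROWS // 2  # rows per reference rectangle


class DetectionError(RuntimeError):
    """A detection stage failed a structural constraint (re-capture advised)."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class DetectionConfig:
    median_kernel: int = 5
    canny_sigma: float = 1.0
    canny_low: float = 0.025
    canny_high: float = 0.055
    morph_kernel: int = 3
    min_contour_area: float = 0.0005  # fraction of image area
    aspect_ratio_min: float = 3.5
    target_aspect_max: float = 1.3
    target_area_tolerance: float = 0.30  # +-30% of the cluster median
    center_band: float = 0.15  # fraction of image height about the midline
    polygon_epsilon: float = 0.02  # fraction of perimeter
    contour_margin: float = 1.25  # px: outward bias of the traced boundary vs the drawn edge
    sample_window: int = 3  # half-width of the averaging window

    def __post_init__(self) -> None:
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be odd and positive")
        if not 0 < self.canny_low < self.canny_high:
            raise ValueError("need 0 < canny_low < canny_high")
        for name in ("morph_kernel", "min_contour_area", "aspect_ratio_min",
                     "center_band", "polygon_epsilon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sample_window < 0:
            raise ValueError("sample_window must be >= 0")


@dataclass(frozen=True)
class Contour:
    """A closed polygonal contour with rectangle-oriented geometry."""

    vertices: np.ndarray  # (4, 2) approximated corners, (x, y)
    boundary: np.ndarray  # dense boundary points, (n, 2)
    area: float
    center: np.ndarray  # (2,)
    axes: np.ndarray  # (2, 2): rows are unit major/minor axes
    side_lengths: np.ndarray  # (2,): extent along major/minor axes

    @property
    def aspect_ratio(self) -> float:
        return float(self.side_lengths[0] / max(self.side_lengths[1], 1e-12))

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @classmethod
    def from_boundary(
        cls, boundary: np.ndarray, epsilon_frac: float, min_tolerance_px: float = 8.0
    ) -> "Contour | None":
        """Build a contour from dense boundary points; None if not a rectangle.

        Keeps only closed polygons that simplify to 4 vertices and are convex.
        The principal axes come from a PCA of the (roughly arc-length uniform)
        boundary points, so the aspect ratio is rotation-invariant; side
        lengths are the crossings of the axes with the polygon boundary.
        """
        closed = np.vstack([boundary, boundary[:1]])
        perimeter = float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())
        # Median filtering rounds stroke corners by a few pixels regardless of
        # contour size, so the tolerance gets a pixel floor; the (arbitrary)
        # start point of a closed curve also survives approximation even
        # mid-edge, so near-collinear vertices are collapsed before counting.
        tolerance = max(epsilon_frac * perimeter, min_tolerance_px)
        approx = measure.approximate_polygon(closed, tolerance=tolerance)
        if np.allclose(approx[0], approx[-1]):
            approx = approx[:-1]
        approx = _collapse_collinear(approx, tolerance)
        if approx.shape[0] != 4:
            return None
        if not _is_convex(approx):
            return None
        if not Polygon(approx).is_valid:
            return None
        # geometry from the minimum rotated rectangle of the convex hull:
        # robust against small notches in the rasterized boundary
        hull_rect = Polygon(boundary).convex_hull.minimum_rotated_rectangle
        corners = np.asarray(hull_rect.exterior.coords)[:4]
        center = corners.mean(axis=0)
        # PCA of the rectangle corners yields exactly the rectangle axes
        centered = corners - center
        cov = centered.T @ centered / 4.0
        evals, evecs = np.linalg.eigh(cov)
        if evals[0] < 1e-9:  # degenerate (line-like) shape
            return None
        order = np.argsort(evals)[::-1]
        axes = evecs[:, order].T  # rows: major, minor
        poly = Polygon(corners)
        sides = []
        for axis in axes:
            pts = _axis_crossings(poly, center, axis)
            if pts is None:
                return None
            sides.append(float(np.linalg.norm(pts[1] - pts[0])))
        return cls(
            vertices=corners,
            boundary=np.asarray(boundary, float),
            area=float(poly.area),
            center=center,
            axes=axes,
            side_lengths=np.asarray(sides, float),
        )


def _collapse_collinear(vertices: np.ndarray, tol: float) -> np.ndarray:
    """Drop vertices lying within ``tol`` of the chord of their neighbors."""
    verts = np.asarray(vertices, float)
    changed = True
    while changed and len(verts) > 3:
        changed = False
        for i in range(len(verts)):
            a, b, c = verts[i - 1], verts[i], verts[(i + 1) % len(verts)]
            chord = c - a
            cross = chord[0] * (b - a)[1] - chord[1] * (b - a)[0]
            dist = abs(cross) / (np.linalg.norm(chord) + 1e-12)
            if dist < tol:
                verts = np.delete(verts, i, axis=0)
                changed = True
                break
    return verts


def _is_convex(vertices: np.ndarray) -> bool:
    n = len(vertices)
    signs = []
    for i in range(n):
        a, b, c = vertices[i], vertices[(i + 1) % n], vertices[(i + 2) % n]
        cross = (b[0] - a[0]) * (c[1] - b[1]) - (b[1] - a[1]) * (c[0] - b[0])
        if abs(cross) > 1e-9:
            signs.append(np.sign(cross))
    return len(set(signs)) == 1


def _axis_crossings(poly: Polygon, center: np.ndarray, axis: np.ndarray):
    """Two intersection points of a centered axis line with the polygon boundary."""
    span = 4.0 * max(poly.bounds[2] - poly.bounds[0], poly.bounds[3] - poly.bounds[1])
    line = LineString([center - span * axis, center + span * axis])
    inter = poly.exterior.intersection(line)
    pts = []
    for geom in getattr(inter, "geoms", [inter]):
        if isinstance(geom, Point):
            pts.append([geom.x, geom.y])
        else:  # collinear overlap: take its endpoints
            coords = np.asarray(geom.coords)
            pts.extend([coords[0], coords[-1]])
    if len(pts) < 2:
        return None
    pts = np.asarray(pts, float)
    t = (pts - center) @ axis
    return np.stack([pts[int(np.argmin(t))], pts[int(np.argmax(t))]])


@dataclass
class SceneLayout:
    """Detected geometry of one capture."""

    upper_reference: Contour
    lower_reference: Contour
    target_contours: list[Contour]
    image_shape: tuple[int, int]  # (height, width)
    reference_positions: np.ndarray | None = None  # (12, 18, 2)
    target_positions: np.ndarray | None = None  # (4, 2)

    def to_dict(self) -> dict:
        def contour_dict(c: Contour) -> dict:
            return {
                "vertices": c.vertices.tolist(),
                "center": c.center.tolist(),
                "area": c.area,
                "aspect_ratio": c.aspect_ratio,
            }

        d = {
            "image_shape": list(self.image_shape),
            "upper_reference": contour_dict(self.upper_reference),
            "lower_reference": contour_dict(self.lower_reference),
            "targets": [contour_dict(c) for c in self.target_contours],
        }
        if self.reference_positions is not None:
            d["reference_positions"] = self.reference_positions.tolist()
        if self.target_positions is not None:
            d["target_positions"] = self.target_positions.tolist()
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def simplify(image: np.ndarray, cfg: DetectionConfig | None = None) -> np.ndarray:
    """Median-filter the capture to suppress noise before edge detection."""
    cfg = cfg or DetectionConfig()
    if cfg.median_kernel > min(image.shape[:2]):
        raise ValueError("median kernel larger than image")
    if image.ndim == 2:
        return ndi.median_filter(image, size=cfg.median_kernel)
    return np.stack(
        [ndi.median_filter(image[..., ch], size=cfg.median_kernel) for ch in range(image.shape[-1])],
        axis=-1,
    )


def detect_edges(image: np.ndarray, cfg: DetectionConfig | None = None) -> np.ndarray:
    """Canny edges of the simplified image, closed morphologically.

    Edges are taken on the per-pixel channel maximum rather than luminance:
    the drawn cell borders are black in every channel, so any colored cell
    keeps a strong max-channel contrast even when its luminance is low.
    """
    cfg = cfg or DetectionConfig()
    gray = image.max(axis=-1) / 255.0 if image.ndim == 3 else image.astype(float) / 255.0
    edges = feature.canny(
        gray, sigma=cfg.canny_sigma, low_threshold=cfg.canny_low, high_threshold=cfg.canny_high
    )
    return ndi.binary_closing(edges, structure=np.ones((cfg.morph_kernel,) * 2, dtype=bool))


def extract_initial_contours(
    edges: np.ndarray, cfg: DetectionConfig | None = None
) -> list[Contour]:
    """Closed rectangular contours from the edge map.

    Each edge loop is filled; connected filled regions (which merge the two
    sides of a drawn border, suppressing inner/outer duplicates) contribute
    their outer boundary.  Regions that do not simplify to a convex
    quadrilateral, or are smaller than ``min_contour_area`` of the image,
    are dropped.
    """
    cfg = cfg or DetectionConfig()
    min_area = cfg.min_contour_area * edges.shape[0] * edges.shape[1]
    filled = ndi.binary_fill_holes(edges)
    labels, n = ndi.label(filled)
    contours: list[Contour] = []
    for idx in range(1, n + 1):
        mask = labels == idx
        if mask.sum() < min_area:
            continue
        outlines = measure.find_contours(mask.astype(float), 0.5)
        if not outlines:
            continue
        boundary_rc = max(outlines, key=len)
        boundary = boundary_rc[:, ::-1]  # (row, col) -> (x, y)
        if np.allclose(boundary[0], boundary[-1]):
            boundary = boundary[:-1]
        contour = Contour.from_boundary(boundary, cfg.polygon_epsilon)
        if contour is not None and contour.area >= min_area:
            contours.append(contour)
    return contours


def _deduplicate_nested(contours: list[Contour]) -> list[Contour]:
    """Drop contours contained in a larger one (inner edge of the same border)."""
    keep = []
    polys = [c.polygon() for c in contours]
    for i, c in enumerate(contours):
        contained = any(
            j != i and contours[j].area > c.area and polys[j].contains(Point(c.center))
            and polys[j].buffer(1.0).contains(polys[i])
            for j in range(len(contours))
        )
        if not contained:
            keep.append(c)
    return keep


def label_contours(
    contours: list[Contour],
    cfg: DetectionConfig | None = None,
    image_shape: tuple[int, int] | None = None,
) -> SceneLayout:
    """Separate reference rectangles from target patches and label them.

    References: aspect ratio above ``aspect_ratio_min`` and center outside
    the center band; the topmost is the upper reference, the bottommost the
    lower.  Targets: square-like contours inside the band, reduced to the
    largest cluster of similar areas, ordered k = 1..4 top to bottom along
    the strip axis.
    """
    cfg = cfg or DetectionConfig()
    if image_shape is None:
        raise ValueError("image_shape is required")
    if not contours:
        raise DetectionError("label", "no contours to label")
    contours = _deduplicate_nested(contours)
    height = image_shape[0]
    midline = height / 2.0
    band = cfg.center_band * height

    refs = [
        c for c in contours
        if c.aspect_ratio > cfg.aspect_ratio_min and abs(c.center[1] - midline) > band
    ]
    if len(refs) < 2:
        raise DetectionError(
            "label",
            f"found {len(refs)} reference candidates "
            f"(need 2 with aspect ratio > {cfg.aspect_ratio_min} outside the center band)",
        )
    refs.sort(key=lambda c: c.center[1])
    upper, lower = refs[0], refs[-1]

    squares = [
        c for c in contours
        if c.aspect_ratio <= cfg.target_aspect_max and abs(c.center[1] - midline) <= band
    ]
    if not squares:
        raise DetectionError("label", "no square candidates near the center line")
    # size-consistency: keep the largest cluster of similar areas
    areas = np.array([c.area for c in squares])
    best_cluster: list[Contour] = []
    for seed_area in areas:
        cluster = [
            c for c in squares
            if abs(c.area - seed_area) <= cfg.target_area_tolerance * seed_area
        ]
        if len(cluster) > len(best_cluster):
            best_cluster = cluster
    if len(best_cluster) != 4:
        raise DetectionError(
            "label",
            f"found {len(best_cluster)} size-consistent target patches near "
            "the center line (need exactly 4)",
        )
    strip_axis = lower.center - upper.center
    strip_axis = strip_axis / np.linalg.norm(strip_axis)
    best_cluster.sort(key=lambda c: float(c.center @ strip_axis))
    return SceneLayout(
        upper_reference=upper,
        lower_reference=lower,
        target_contours=best_cluster,
        image_shape=tuple(image_shape[:2]),
    )


def _oriented_axes(contour: Contour) -> np.ndarray:
    """Major axis pointing toward +x (column 1 nearest the left edge), minor toward +y."""
    major, minor = contour.axes[0].copy(), contour.axes[1].copy()
    if major[0] < 0:
        major = -major
    # make the minor axis the +90 degree rotation of major, then point it down
    minor = np.array([-major[1], major[0]])
    if minor[1] < 0:
        minor = -minor
    return np.stack([major, minor])


def _rectangle_grid(
    contour: Contour, rows: int, cols: int, margin: float = 0.0
) -> np.ndarray:
    """(rows, cols, 2) cell centers placed in the contour's principal frame.

    ``margin`` shrinks the frame on every side to undo the outward bias of
    the traced boundary relative to the drawn rectangle edge.
    """
    axes = _oriented_axes(contour)
    poly = contour.polygon()
    maj = _axis_crossings(poly, contour.center, axes[0])
    mino = _axis_crossings(poly, contour.center, axes[1])
    if maj is None or mino is None:
        raise DetectionError("grid", "principal axes do not cross the contour")
    base = (maj.mean(axis=0) + mino.mean(axis=0)) / 2.0
    major_span = maj[1] - maj[0]
    minor_span = mino[1] - mino[0]
    for span in (major_span, minor_span):
        length = np.linalg.norm(span)
        if length > 4 * margin:
            span *= 1.0 - 2.0 * margin / length
    fc = (np.arange(cols) + 0.5) / cols - 0.5
    fr = (np.arange(rows) + 0.5) / rows - 0.5
    return (
        base[None, None, :]
        + fr[:, None, None] * minor_span[None, None, :]
        + fc[None, :, None] * major_span[None, None, :]
    )


def place_sampling_grid(
    layout: SceneLayout, cfg: DetectionConfig | None = None
) -> SceneLayout:
    """Fill in the 6x18 sampling positions per reference and the 4 target positions.

    Target positions are anchored on the midline between the two reference
    regions (their averaged center and major-axis slope); each is snapped to
    the nearest detected target-contour center when one is available.
    """
    cfg = cfg or DetectionConfig()
    upper = _rectangle_grid(layout.upper_reference, HALF_ROWS, GRID_COLS, cfg.contour_margin)
    lower = _rectangle_grid(layout.lower_reference, HALF_ROWS, GRID_COLS, cfg.contour_margin)
    reference_positions = np.concatenate([upper, lower], axis=0)

    mid_center = (layout.upper_reference.center + layout.lower_reference.center) / 2.0
    ax_u = _oriented_axes(layout.upper_reference)[0]
    ax_l = _oriented_axes(layout.lower_reference)[0]
    mean_major = ax_u + ax_l
    mean_major = mean_major / np.linalg.norm(mean_major)
    strip_axis = np.array([-mean_major[1], mean_major[0]])
    if strip_axis[1] < 0:
        strip_axis = -strip_axis
    gap = float(np.linalg.norm(layout.lower_reference.center - layout.upper_reference.center))
    offsets = (np.arange(4) - 1.5) / 4.0 * (gap / 2.0)
    midline_positions = mid_center[None, :] + offsets[:, None] * strip_axis[None, :]

    target_positions = np.empty((4, 2))
    centers = np.array([c.center for c in layout.target_contours])
    for k in range(4):
        if len(centers):
            target_positions[k] = centers[
                int(np.argmin(np.linalg.norm(centers - midline_positions[k], axis=1)))
            ]
        else:
            target_positions[k] = midline_positions[k]
    if len(centers) == 4:
        # trust the detected contour centers outright, in strip order
        target_positions = centers

    h, w = layout.image_shape
    all_pos = np.vstack([reference_positions.reshape(-1, 2), target_positions])
    if (all_pos < -0.5).any() or (all_pos[:, 0] > w - 0.5).any() or (all_pos[:, 1] > h - 0.5).any():
        raise DetectionError("grid", "sampling positions fall outside the image")
    layout.reference_positions = reference_positions
    layout.target_positions = target_positions
    return layout


def retrieve_colors(
    image: np.ndarray, layout: SceneLayout, cfg: DetectionConfig | None = None
) -> tuple[ReferenceGrid, TargetPatchColors]:
    """Sample the 216 reference colors and 4 target colors from the image.

    Each color is the mean of a (2*sample_window+1)^2 window in linear RGB,
    converted to u'v'.  Grid ordering is row-major: upper reference rows
    1-6, then lower rows 7-12, columns left to right along the major axis.
    """
    cfg = cfg or DetectionConfig()
    if layout.reference_positions is None or layout.target_positions is None:
        raise ValueError("layout has no sampling positions; call place_sampling_grid first")
    ref = np.empty((GRID_ROWS, GRID_COLS, 2))
    for i in range(GRID_ROWS):
        for j in range(GRID_COLS):
            uv = mean_patch_uv(image, layout.reference_positions[i, j], cfg.sample_window)
            ref[i, j] = (uv.u, uv.v)
    tgt = np.empty((4, 2))
    for k in range(4):
        uv = mean_patch_uv(image, layout.target_positions[k], cfg.sample_window)
        tgt[k] = (uv.u, uv.v)
    return ReferenceGrid(ref), TargetPatchColors(tgt)


def detect_scene(
    image: np.ndarray, cfg: DetectionConfig | None = None
) -> tuple[SceneLayout, ReferenceGrid, TargetPatchColors]:
    """Run all six steps on a capture image."""
    cfg = cfg or DetectionConfig()
    simplified = simplify(image, cfg)
    edges = detect_edges(simplified, cfg)
    contours = extract_initial_contours(edges, cfg)
    layout = label_contours(contours, cfg, image.shape[:2])
    layout = place_sampling_grid(layout, cfg)
    grid, targets = retrieve_colors(simplified, layout, cfg)
    return layout, grid, targets


def draw_overlay(image: np.ndarray, layout: SceneLayout) -> np.ndarray:
    """Paint detected contours and sampling positions for visual inspection."""
    out = image.copy()
    h, w = out.shape[:2]

    def paint(points: np.ndarray, color) -> None:
        pts = np.round(points).astype(int)
        ok = (pts[:, 0] >= 0) & (pts[:, 0] < w) & (pts[:, 1] >= 0) & (pts[:, 1] < h)
        out[pts[ok, 1], pts[ok, 0]] = color

    for contour in [layout.upper_reference, layout.lower_reference, *layout.target_contours]:
        paint(contour.boundary, (255, 0, 0))
    if layout.reference_positions is not None:
        pos = layout.reference_positions.reshape(-1, 2)
        for dx, dy in [(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)]:
            paint(pos + [dx, dy], (0, 255, 0))
    if layout.target_positions is not None:
        for dx, dy in [(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)]:
            paint(layout.target_positions + [dx, dy], (0, 0, 255))
    return out
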
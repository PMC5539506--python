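"""Build the stored calibration product from 15 comparison-chart captures.

For every integer pH index P = 0..14 a color-converting model F_P is fitted
from that capture's 216 reference colors onto the pivot capture's reference
colors, and applied to the capture's 4 target-patch colors.  Each patch then
has 15 adapted colors indexed by P; a smoothing spline (squared misfit plus
``lambda`` times the integrated squared second derivative, solved per u'/v'
channel) interpolates them onto the 0.1-pH grid, yielding 4 curves of 141
points.  The stored product is the pivot reference grid plus those curves.

The smoothing penalty multiplies the raw (un-normalized) sum of squared
errors; note that library smoothing splines often divide the error term by
the number of points, which changes the meaning of ``lambda``.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import scipy.linalg as sla
from scipy.interpolate import CubicSpline

from .adaptation import CorrespondenceSet, IRLSConfig, fit_l1

logger = logging.getLogger(__name__)

__all__ = [
    "N_REFERENCE",
    "ReferenceGrid",
    "TargetPatchColors",
    "ChartCapture",
    "SplineConfig",
    "CalibrationData",
    "smoothing_spline_1d",
    "interpolate_curve",
    "calibrate",
]

GRID_ROWS = 12
GRID_COLS = 18
N_REFERENCE = GRID_ROWS * GRID_COLS  # 216
N_PATCHES = 4
PH_INDEXES = tuple(range(15))


@dataclass(frozen=True)
class ReferenceGrid:
    """12x18 grid of reference u'v' colors (upper half rows 1-6, lower 7-12)."""

    colors: np.ndarray  # (12, 18, 2)

    def __post_init__(self) -> None:
        colors = np.asarray(self.colors, dtype=float)
        object.__setattr__(self, "colors", colors)
        if colors.shape != (GRID_ROWS, GRID_COLS, 2):
            raise ValueError(f"expected shape {(GRID_ROWS, GRID_COLS, 2)}, got {colors.shape}")
        if not np.all(np.isfinite(colors)):
            raise ValueError("reference grid contains non-finite colors")

    @property
    def n_entries(self) -> int:
        return self.colors.shape[0] * self.colors.shape[1]

    def flat(self) -> np.ndarray:
        """Row-major (i then j) view of shape (216, 2)."""
        return self.colors.reshape(-1, 2)


@dataclass(frozen=True)
class TargetPatchColors:
    """u'v' colors of the four strip patches, k = 1..4."""

    colors: np.ndarray  # (4, 2)

    def __post_init__(self) -> None:
        colors = np.asarray(self.colors, dtype=float)
        object.__setattr__(self, "colors", colors)
        if colors.shape != (N_PATCHES, 2):
            raise ValueError(f"expected shape {(N_PATCHES, 2)}, got {colors.shape}")
        if not np.all(np.isfinite(colors)):
            raise ValueError("target colors contain non-finite values")


@dataclass(frozen=True)
class ChartCapture:
    """One comparison-chart capture, tagged with its integer pH index."""

    ph_index: int
    reference: ReferenceGrid
    target: TargetPatchColors

    def __post_init__(self) -> None:
        if self.ph_index not in PH_INDEXES:
            raise ValueError(f"ph_index {self.ph_index} outside 0..14")


@dataclass(frozen=True)
class SplineConfig:
    lambda_smooth: float = 3.0 / 7.0
    grid_start: float = 0.0
    grid_stop: float = 14.0
    grid_step: float = 0.1

    def __post_init__(self) -> None:
        if self.lambda_smooth < 0:
            raise ValueError("lambda_smooth must be >= 0")
        n = (self.grid_stop - self.grid_start) / self.grid_step
        if abs(n - round(n)) > 1e-9:
            raise ValueError("grid_step must divide the grid range")

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.grid_stop - self.grid_start) / self.grid_step))
        return np.linspace(self.grid_start, self.grid_stop, n + 1)


def smoothing_spline_1d(x: np.ndarray, y: np.ndarray, lam: float) -> CubicSpline:
    """Natural cubic smoothing spline minimizing sum((y - f(x))^2) + lam * int f''^2.

    Solved in the Reinsch/Green-Silverman value form: the fitted knot values g
    minimize ``||y - g||^2 + lam * g^T D^T W^-1 D g`` and the curve is the
    natural cubic interpolant of g.  The penalized solve is posed as a stacked
    least-squares problem, which stays accurate for very large ``lam`` (the
    limit is the least-squares straight line) where generic solvers drift.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if lam < 0:
        raise ValueError("lam must be >= 0")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 knots")
    if np.any(np.diff(x) <= 0):
        raise ValueError("knots must be strictly increasing")
    if lam == 0:
        return CubicSpline(x, y, bc_type="natural")
    h = np.diff(x)
    d = np.zeros((n - 2, n))
    rows = np.arange(n - 2)
    d[rows, rows] = 1.0 / h[:-1]
    d[rows, rows + 1] = -1.0 / h[:-1] - 1.0 / h[1:]
    d[rows, rows + 2] = 1.0 / h[1:]
    w = np.zeros((n - 2, n - 2))
    w[rows, rows] = (h[:-1] + h[1:]) / 3.0
    w[rows[:-1], rows[:-1] + 1] = h[1:-1] / 6.0
    w[rows[:-1] + 1, rows[:-1]] = h[1:-1] / 6.0
    lw = sla.cholesky(w, lower=True)
    half_penalty = sla.solve_triangular(lw, d, lower=True)
    a = np.vstack([np.eye(n), np.sqrt(lam) * half_penalty])
    b = np.concatenate([y, np.zeros(n - 2)])
    g, *_ = np.linalg.lstsq(a, b, rcond=None)
    return CubicSpline(x, g, bc_type="natural")


def interpolate_curve(points: np.ndarray, spline: SplineConfig | None = None) -> np.ndarray:
    """Interpolate 15 per-index u'v' points onto the 0.1-pH grid (141 x 2).

    The vector-valued smoothing energy separates over the two channels, so
    each channel is fitted with an independent scalar smoothing spline.
    """
    spline = spline or SplineConfig()
    points = np.asarray(points, dtype=float)
    if points.shape != (len(PH_INDEXES), 2):
        raise ValueError(f"expected shape {(len(PH_INDEXES), 2)}, got {points.shape}")
    if not np.all(np.isfinite(points)):
        raise ValueError("curve points contain non-finite values")
    x = np.asarray(PH_INDEXES, dtype=float)
    grid = spline.grid
    out = np.empty((len(grid), 2))
    for ch in range(2):
        fit = smoothing_spline_1d(x, points[:, ch], spline.lambda_smooth)
        out[:, ch] = fit(grid)
        if logger.isEnabledFor(logging.DEBUG):
            resid = float(np.sum((fit(x) - points[:, ch]) ** 2))
            fine = np.linspace(x[0], x[-1], 4001)
            curv = float(np.trapezoid(fit.derivative(2)(fine) ** 2, fine))
            logger.debug(
                "channel %d: E_error=%.3e, E_smooth=%.3e (lambda=%.4g)",
                ch, resid, curv, spline.lambda_smooth,
            )
    return out


@dataclass(frozen=True)
class CalibrationData:
    """Stored calibration product: pivot reference colors + per-patch curves."""

    pivot_index: int
    pivot_reference: ReferenceGrid
    curves: np.ndarray  # (4, 141, 2)
    spline: SplineConfig = field(default_factory=SplineConfig)

    def __post_init__(self) -> None:
        curves = np.asarray(self.curves, dtype=float)
        object.__setattr__(self, "curves", curves)
        expected = (N_PATCHES, len(self.spline.grid), 2)
        if curves.shape != expected:
            raise ValueError(f"expected curves of shape {expected}, got {curves.shape}")
        if not np.all(np.isfinite(curves)):
            raise ValueError("curves contain non-finite values")

    @property
    def grid(self) -> np.ndarray:
        return self.spline.grid

    def to_dict(self) -> dict:
        return {
            "pivot": self.pivot_index,
            "pivot_reference": [[float(u), float(v)] for u, v in self.pivot_reference.flat()],
            "curves": [[[float(u), float(v)] for u, v in patch] for patch in self.curves],
            "grid": {
                "start": self.spline.grid_start,
                "stop": self.spline.grid_stop,
                "step": self.spline.grid_step,
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationData":
        grid = d["grid"]
        spline = SplineConfig(
            grid_start=grid["start"], grid_stop=grid["stop"], grid_step=grid["step"]
        )
        ref = np.asarray(d["pivot_reference"], float).reshape(GRID_ROWS, GRID_COLS, 2)
        return cls(
            pivot_index=int(d["pivot"]),
            pivot_reference=ReferenceGrid(ref),
            curves=np.asarray(d["curves"], float),
            spline=spline,
        )

    @classmethod
    def from_json(cls, s: str) -> "CalibrationData":
        return cls.from_dict(json.loads(s))

    def curves_to_csv(self, path) -> None:
        """Write the curves as CSV rows (p, k, u, v) for plotting."""
        grid = self.grid
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["p", "k", "u", "v"])
            for k in range(N_PATCHES):
                for p, (u, v) in zip(grid, self.curves[k]):
                    writer.writerow([f"{p:.1f}", k + 1, repr(float(u)), repr(float(v))])


def calibrate(
    captures: Iterable[ChartCapture],
    pivot: int = 7,
    spline: SplineConfig | None = None,
    irls: IRLSConfig | None = None,
) -> CalibrationData:
    """Run the calibration step over the 15 chart captures.

    The pivot capture is passed through its own (near-identity) fitted model
    like every other capture, so all 15 are processed uniformly.
    """
    spline = spline or SplineConfig()
    irls = irls or IRLSConfig()
    by_index: dict[int, ChartCapture] = {}
    for cap in captures:
        if cap.ph_index in by_index:
            raise ValueError(f"duplicate capture for pH index {cap.ph_index}")
        by_index[cap.ph_index] = cap
    missing = sorted(set(PH_INDEXES) - set(by_index))
    if missing:
        raise ValueError(f"missing captures for pH indexes {missing}")
    if pivot not in by_index:
        raise ValueError(f"pivot index {pivot} not among captures")

    pivot_ref = by_index[pivot].reference
    adapted = np.empty((len(PH_INDEXES), N_PATCHES, 2))
    for p in PH_INDEXES:
        cap = by_index[p]
        model = fit_l1(
            CorrespondenceSet(cap.reference.flat(), pivot_ref.flat()), irls
        )
        adapted[p] = model.apply_array(cap.target.colors)
        logger.debug(
            "F_%d fitted; max |residual| on reference colors: %.3e",
            p,
            float(np.abs(model.apply_array(cap.reference.flat()) - pivot_ref.flat()).max()),
        )

    curves = np.stack(
        [interpolate_curve(adapted[:, k, :], spline) for k in range(N_PATCHES)]
    )
    return CalibrationData(
        pivot_index=pivot, pivot_reference=pivot_ref, curves=curves, spline=spline
    )
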
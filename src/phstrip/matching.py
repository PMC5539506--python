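"""Measurement step: adapt a capture into the calibration frame, match pH.

The capture's 216 reference colors are fitted onto the stored pivot
reference colors, the resulting model is applied to the 4 raw strip-patch
colors, and the pH is the grid point whose stored curve colors minimize the
summed L1 chromaticity distance over the four patches.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np

from .adaptation import CorrespondenceSet, IRLSConfig, fit_l1
from .calibration import CalibrationData, ReferenceGrid, TargetPatchColors

__all__ = ["MeasurementCapture", "PHEstimate", "measure", "summarize_replicates"]


@dataclass(frozen=True)
class MeasurementCapture:
    """Reference grid and raw target-patch colors of one measurement image."""

    reference: ReferenceGrid
    raw_target: TargetPatchColors


@dataclass(frozen=True)
class PHEstimate:
    ph: float
    match_cost: float
    per_patch_cost: np.ndarray  # (4,) at the argmin
    calibrated_target: TargetPatchColors  # adapted (not raw) patch colors
    cost_profile: np.ndarray  # (141,) total cost per grid point
    grid: np.ndarray

    def __float__(self) -> float:
        return self.ph


def measure(
    capture: MeasurementCapture,
    calib: CalibrationData,
    irls: IRLSConfig | None = None,
    refine: bool = False,
) -> PHEstimate:
    """Estimate pH for one capture against stored calibration data.

    Ties in the cost profile break toward the lowest pH.  With
    ``refine=True`` a parabolic interpolation of the three costs around the
    grid minimum is reported instead of the raw grid value (off by default;
    reported results use the 0.1 grid).
    """
    irls = irls or IRLSConfig()
    grid = calib.grid
    if grid.size == 0:
        raise ValueError("calibration grid is empty")
    model = fit_l1(
        CorrespondenceSet(capture.reference.flat(), calib.pivot_reference.flat()),
        irls,
    )
    adapted = model.apply_array(capture.raw_target.colors)  # (4, 2)
    # cost(p) = sum_k |du'| + |dv'| against the stored curves (4, 141, 2)
    per_patch = np.abs(calib.curves - adapted[:, None, :]).sum(axis=2)  # (4, 141)
    profile = per_patch.sum(axis=0)  # (141,)
    idx = int(np.argmin(profile))  # np.argmin returns the first (lowest-p) tie
    ph = float(grid[idx])
    if refine and 0 < idx < len(grid) - 1:
        c0, c1, c2 = profile[idx - 1], profile[idx], profile[idx + 1]
        denom = c0 - 2 * c1 + c2
        if denom > 0:
            ph += float(grid[1] - grid[0]) * 0.5 * float(c0 - c2) / float(denom)
    return PHEstimate(
        ph=ph,
        match_cost=float(profile[idx]),
        per_patch_cost=per_patch[:, idx].copy(),
        calibrated_target=TargetPatchColors(adapted),
        cost_profile=profile,
        grid=grid,
    )


def _round2(d: Decimal) -> float:
    return float(d.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def summarize_replicates(
    estimates: Sequence[PHEstimate | float], ideal_ph: float
) -> tuple[float, float]:
    """Average absolute error and population standard deviation of replicates.

    Estimates live on the 0.1 grid, so statistics are computed in exact
    decimal arithmetic on the 0.1-quantized values: the mean absolute
    deviation from ``ideal_ph`` and the divide-by-n standard deviation, both
    rounded half-up to 2 decimals (the convention that reproduces published
    replicate tables).
    """
    values = [float(e) for e in estimates]
    if not values:
        raise ValueError("need at least one estimate")
    dec = [Decimal(f"{v:.1f}") for v in values]
    ideal = Decimal(str(ideal_ph))
    n = len(dec)
    avg_abs_error = _round2(sum(abs(d - ideal) for d in dec) / n)
    mean = sum(dec) / n
    variance = sum((d - mean) ** 2 for d in dec) / n
    std_dev = _round2(variance.sqrt())
    return avg_abs_error, std_dev
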
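"""Robust polynomial color adaptation between two sets of u'v' colors.

The mapping is a third-order bivariate polynomial with 10 coefficients per
output channel (20 total).  The two channels share the monomial basis but
are fitted independently.  Fitting minimizes the sum of absolute residuals
(L1) via iteratively reweighted least squares (IRLS): starting from unit
weights, each iteration solves a weighted least-squares problem and resets
each weight to ``1 / max(delta, |residual|)``.  The iteration count is
fixed (no convergence test) unless an explicit tolerance is supplied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .colorspace import UVColor

__all__ = [
    "BASIS_TAG",
    "N_PARAMETERS",
    "PolyColorModel",
    "CorrespondenceSet",
    "IRLSConfig",
    "FitError",
    "design_row",
    "design_matrix",
    "fit_l1",
    "apply_model",
    "l1_cost",
]

# Monomial order of the 10-term basis; serialized models carry this tag so
# coefficient vectors stay comparable across implementations.
BASIS_TAG = "uv-cubic-10term-v1"
N_BASIS = 10
N_PARAMETERS = 2 * N_BASIS


class FitError(ValueError):
    """Raised when a color-adaptation fit cannot be performed."""


def design_row(c: UVColor | Sequence[float]) -> np.ndarray:
    """The 10 monomial basis values [u, v, 1, u2, v2, uv, u3, v3, u2v, uv2]."""
    if isinstance(c, UVColor):
        u, v = c.u, c.v
    else:
        u, v = float(c[0]), float(c[1])
    return design_matrix(np.array([[u, v]]))[0]

def design_matrix(uv: np.ndarray) -> np.ndarray:
    """Design matrix with one basis row per (u, v) pair; shape (n, 10)."""
    uv = np.asarray(uv, dtype=float)
    u, v = uv[..., 0], uv[..., 1]
    cols = [u, v, np.ones_like(u), u * u, v * v, u * v,
            u**3, v**3, u * u * v, u * v * v]
    return np.stack(cols, axis=-1)


@dataclass(frozen=True)
class PolyColorModel:
    """Third-order polynomial u'v' color-converting model (20 parameters)."""

    a_u: np.ndarray
    a_v: np.ndarray

    def __post_init__(self) -> None:
        a_u = np.asarray(self.a_u, dtype=float)
        a_v = np.asarray(self.a_v, dtype=float)
        object.__setattr__(self, "a_u", a_u)
        object.__setattr__(self, "a_v", a_v)
        if a_u.shape != (N_BASIS,) or a_v.shape != (N_BASIS,):
            raise ValueError("each channel needs exactly 10 coefficients")
        if not (np.all(np.isfinite(a_u)) and np.all(np.isfinite(a_v))):
            raise ValueError("model coefficients must be finite")

    @property
    def n_parameters(self) -> int:
        return self.a_u.size + self.a_v.size

    @classmethod
    def identity(cls) -> "PolyColorModel":
        a_u = np.zeros(N_BASIS)
        a_v = np.zeros(N_BASIS)
        a_u[0] = 1.0  # u_d = u_s
        a_v[1] = 1.0  # v_d = v_s
        return cls(a_u, a_v)

    def to_dict(self) -> dict:
        return {
            "a_u": [float(x) for x in self.a_u],
            "a_v": [float(x) for x in self.a_v],
            "basis": BASIS_TAG,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "PolyColorModel":
        if d.get("basis", BASIS_TAG) != BASIS_TAG:
            raise ValueError(f"unknown basis tag {d.get('basis')!r}")
        return cls(np.asarray(d["a_u"], float), np.asarray(d["a_v"], float))

    @classmethod
    def from_json(cls, s: str) -> "PolyColorModel":
        return cls.from_dict(json.loads(s))

    def apply_array(self, uv: np.ndarray) -> np.ndarray:
        """Map an (..., 2) array of u'v' points through the model."""
        x = design_matrix(uv)
        return np.stack([x @ self.a_u, x @ self.a_v], axis=-1)

    def __call__(self, c: UVColor) -> UVColor:
        out = self.apply_array(np.array([[c.u, c.v]]))[0]
        return UVColor(float(out[0]), float(out[1]))


@dataclass(frozen=True)
class CorrespondenceSet:
    """Paired source/destination u'v' colors; arrays of shape (n, 2), n >= 10."""

    sources: np.ndarray
    destinations: np.ndarray

    def __post_init__(self) -> None:
        src = np.asarray(self.sources, dtype=float).reshape(-1, 2)
        dst = np.asarray(self.destinations, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "sources", src)
        object.__setattr__(self, "destinations", dst)
        if src.shape != dst.shape:
            raise ValueError(
                f"sources ({src.shape[0]}) and destinations ({dst.shape[0]}) differ in length"
            )
        if src.shape[0] < N_BASIS:
            raise FitError(f"need at least {N_BASIS} correspondences, got {src.shape[0]}")
        if not (np.all(np.isfinite(src)) and np.all(np.isfinite(dst))):
            raise FitError("correspondences contain non-finite values")

    def __len__(self) -> int:
        return self.sources.shape[0]


@dataclass(frozen=True)
class IRLSConfig:
    delta: float = 0.01
    iterations: int = 20
    # Optional early stop on coefficient change; disabled by default to keep
    # the fixed-iteration contract.
    tolerance: float | None = None

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def _irls_channel(x: np.ndarray, y: np.ndarray, cfg: IRLSConfig) -> np.ndarray:
    w = np.ones(len(y))
    a = np.zeros(x.shape[1])
    for _ in range(cfg.iterations):
        sw = np.sqrt(w)
        sol, _, rank, _ = np.linalg.lstsq(x * sw[:, None], y * sw, rcond=None)
        if rank < x.shape[1]:
            raise FitError(
                f"design matrix rank {rank} < {x.shape[1]}: source colors are degenerate"
            )
        if cfg.tolerance is not None and np.max(np.abs(sol - a)) < cfg.tolerance:
            a = sol
            break
        a = sol
        w = 1.0 / np.maximum(cfg.delta, np.abs(y - x @ a))
    return a


def fit_l1(data: CorrespondenceSet, cfg: IRLSConfig | None = None) -> PolyColorModel:
    """Fit the 20-parameter model by L1 (least absolute deviation) IRLS.

    Each output channel is an independent regression on the shared basis;
    weights are likewise maintained per channel.
    """
    cfg = cfg or IRLSConfig()
    x = design_matrix(data.sources)
    a_u = _irls_channel(x, data.destinations[:, 0], cfg)
    a_v = _irls_channel(x, data.destinations[:, 1], cfg)
    return PolyColorModel(a_u, a_v)


def apply_model(model: PolyColorModel, c: UVColor) -> UVColor:
    """Apply a fitted model to one color (see ``PolyColorModel.apply_array``)."""
    return model(c)


def l1_cost(model: PolyColorModel, data: CorrespondenceSet) -> float:
    """Sum of absolute residuals over both channels of a correspondence set."""
    pred = model.apply_array(data.sources)
    return float(np.abs(pred - data.destinations).sum())
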
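"""Benefit-regime phase diagrams over the (x, y, z) parameter cube.

For each point of a grid over [0, 1]^3 the inhibitor's benefit regime
(always / never / conditionally beneficial, or neutral) is determined from
the closed-form threshold; the critical-d boundary surface z*(x, y) for a
given inhibitor efficacy d is extracted by bracketed root finding.  Lower
specificity ratios alpha (more ara-CTPase-specific inhibitors) enlarge the
beneficial region monotonically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import COMPARISON_TOL, Regime, threshold_formula

__all__ = [
    "PhaseGrid",
    "classify_grid",
    "boundary_surface",
    "region_fractions",
    "surface_frame",
]

#: Default per-axis grid resolution (~7e4 closed-form evaluations).
DEFAULT_RESOLUTION = 41

_REGIME_ORDER = (
    Regime.ALWAYS_BENEFICIAL,
    Regime.NEVER_BENEFICIAL,
    Regime.CONDITIONAL,
    Regime.NEUTRAL,
)
_CODE = {r: i for i, r in enumerate(_REGIME_ORDER)}


@dataclass(frozen=True)
class PhaseGrid:
    """Regime labels (and thresholds where defined) on a cartesian grid.

    ``labels`` holds integer regime codes (see ``regimes`` for the order)
    with shape (len(x), len(y), len(z)); ``thresholds`` the critical d at
    each point (+/-inf sentinels in degenerate branches, NaN for NEUTRAL).
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    labels: np.ndarray
    thresholds: np.ndarray
    alpha: float
    regimes: tuple[Regime, ...] = _REGIME_ORDER

    def regime_at(self, i: int, j: int, k: int) -> Regime:
        return self.regimes[self.labels[i, j, k]]

    def beneficial_mask(self, d: float) -> np.ndarray:
        """Points where an inhibitor of efficacy d strictly helps."""
        always = self.labels == _CODE[Regime.ALWAYS_BENEFICIAL]
        cond = self.labels == _CODE[Regime.CONDITIONAL]
        return always | (cond & (self.thresholds < d))

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: x, y, z, regime, threshold, alpha."""
        xg, yg, zg = np.meshgrid(self.x, self.y, self.z, indexing="ij")
        return pd.DataFrame(
            {
                "x": xg.ravel(),
                "y": yg.ravel(),
                "z": zg.ravel(),
                "regime": [self.regimes[c].value for c in self.labels.ravel()],
                "threshold": self.thresholds.ravel(),
                "alpha": self.alpha,
            }
        )


def classify_grid(
    resolution: int | tuple[int, int, int] = DEFAULT_RESOLUTION,
    alpha: float = 1.0,
    axes: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> PhaseGrid:
    """Classify the inhibitor's benefit regime over an (x, y, z) grid.

    ``resolution`` gives the number of evenly spaced points per axis over
    [0, 1] (boundary values included; degenerate branches handle the faces);
    explicit ``axes`` override it.  Deterministic closed-form evaluation.
    """
    if axes is not None:
        x_ax, y_ax, z_ax = (np.asarray(a, dtype=float) for a in axes)
    else:
        if isinstance(resolution, int):
            resolution = (resolution, resolution, resolution)
        if any(r < 2 for r in resolution):
            raise ValueError("resolution must be >= 2 per axis")
        x_ax, y_ax, z_ax = (np.linspace(0.0, 1.0, r) for r in resolution)
    for name, ax in (("x", x_ax), ("y", y_ax), ("z", z_ax)):
        if np.any(np.diff(ax) <= 0):
            raise ValueError(f"{name} axis must be strictly increasing")

    x, y, z = np.meshgrid(x_ax, y_ax, z_ax, indexing="ij")
    slope = alpha * x * y * z
    g0 = x * z + alpha * x * y - alpha * y - (1.0 + alpha) * x * y * z
    with np.errstate(divide="ignore", invalid="ignore"):
        t = threshold_formula(x, y, z, alpha)

    labels = np.empty(x.shape, dtype=np.int8)
    thresholds = np.empty(x.shape)
    interior = slope > COMPARISON_TOL
    # degenerate faces: gain is d*g0 with g0 constant in d
    deg = ~interior
    neutral = deg & (np.abs(g0) <= COMPARISON_TOL)
    labels[neutral] = _CODE[Regime.NEUTRAL]
    thresholds[neutral] = np.nan
    deg_always = deg & (g0 > COMPARISON_TOL)
    labels[deg_always] = _CODE[Regime.ALWAYS_BENEFICIAL]
    thresholds[deg_always] = -np.inf
    deg_never = deg & (g0 < -COMPARISON_TOL)
    labels[deg_never] = _CODE[Regime.NEVER_BENEFICIAL]
    thresholds[deg_never] = np.inf
    # interior: classify by the threshold
    thresholds[interior] = t[interior]
    labels[interior & (t <= 0.0)] = _CODE[Regime.ALWAYS_BENEFICIAL]
    labels[interior & (t >= 1.0)] = _CODE[Regime.NEVER_BENEFICIAL]
    labels[interior & (t > 0.0) & (t < 1.0)] = _CODE[Regime.CONDITIONAL]
    return PhaseGrid(x=x_ax, y=y_ax, z=z_ax, labels=labels, thresholds=thresholds,
                     alpha=float(alpha))


def boundary_surface(
    x_grid: np.ndarray,
    y_grid: np.ndarray,
    d: float,
    alpha: float = 1.0,
    tol: float = 1e-10,
) -> np.ndarray:
    """Critical surface z*(x, y) where the benefit threshold equals d.

    The threshold is strictly decreasing in z for x < 1 (its z-dependence is
    (1/x - 1)/z up to a constant), so a sign change of threshold - d over
    z in (0, 1] brackets a unique root, found by Brent's method to ``tol``.
    NaN marks (x, y) cells with no root in (0, 1] — absence of a boundary is
    data (the whole z-range is on one side), not an error.
    """
    x_grid = np.asarray(x_grid, dtype=float)
    y_grid = np.asarray(y_grid, dtype=float)
    z_lo = 1e-12
    out = np.full((len(x_grid), len(y_grid)), np.nan)
    for i, x in enumerate(x_grid):
        for j, y in enumerate(y_grid):
            if x <= 0.0 or y <= 0.0 or alpha <= 0.0:
                continue

            def f(z: float) -> float:
                return float(threshold_formula(x, y, z, alpha)) - d

            f_lo, f_hi = f(z_lo), f(1.0)
            if f_lo == 0.0:
                out[i, j] = z_lo
            elif f_hi == 0.0:
                out[i, j] = 1.0
            elif f_lo * f_hi < 0.0:
                out[i, j] = brentq(f, z_lo, 1.0, xtol=tol)
    return out


def region_fractions(grid: PhaseGrid) -> dict[Regime, float]:
    """Fraction of grid points in each regime (sums to 1)."""
    total = grid.labels.size
    return {
        regime: float(np.count_nonzero(grid.labels == _CODE[regime])) / total
        for regime in grid.regimes
    }


def surface_frame(
    x_grid: np.ndarray, y_grid: np.ndarray, d: float, alpha: float = 1.0
) -> pd.DataFrame:
    """Long-format (x, y, z_star, d, alpha) export of a boundary surface."""
    z_star = boundary_surface(x_grid, y_grid, d, alpha)
    xg, yg = np.meshgrid(np.asarray(x_grid, float), np.asarray(y_grid, float),
                         indexing="ij")
    return pd.DataFrame(
        {"x": xg.ravel(), "y": yg.ravel(), "z_star": z_star.ravel(),
         "d": d, "alpha": alpha}
    )
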
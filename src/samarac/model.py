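"""Closed-form efficacy algebra for ara-C treatment of AML under SAMHD1.

The model treats one treatment cycle of a single AML clone as two
statistically independent inhibitory routes:

* the ara-C route, which kills a cell with probability ``x`` when SAMHD1
  does not interfere, reduced to ``x_red = (1 - z) * x`` by SAMHD1's
  ara-CTPase activity (``z`` is the fractional reduction of ara-C efficacy);
* the direct SAMHD1 tumour-suppressor route, which kills a cell with
  probability ``y``.

A cell survives only if it escapes both routes, so the cycle efficacy is

    e = 1 - (1 - (1 - z) * x) * (1 - y) = y + x - x*z - y*x + x*y*z.

A SAMHD1 inhibitor of efficacy ``d`` (against the ara-CTPase function) and
specificity ``alpha = d_y / d_z`` (how strongly it also hits the
tumour-suppressor function) rescales ``y`` and ``z`` to

    y_red = (1 - alpha*d) * y,    z_red = (1 - d) * z,

and the combined efficacy is the base formula evaluated at the reduced
values.  Because inhibiting SAMHD1 removes a tumour suppressor as well as a
resistance factor, adding the inhibitor is only beneficial above a critical
efficacy

    d* = (1 + alpha)/alpha - 1/z - 1/(alpha*y) + 1/(x*z),

which for a symmetric inhibitor (alpha = 1) reduces to
``2 - 1/z - 1/y + 1/(x*z)``.  All quantities here are probabilities
(fractions in [0, 1]); everything is closed form and deterministic except
:func:`monte_carlo_efficacy`, a per-cell simulation oracle of the same
two-route survival model.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "VALIDATION_TOL",
    "COMPARISON_TOL",
    "DEFAULT_SEED",
    "DegenerateParameterError",
    "CloneParams",
    "DrugSpec",
    "ReducedParams",
    "Regime",
    "RegimeClassification",
    "MonteCarloResult",
    "efficacy_formula",
    "combined_formula",
    "threshold_formula",
    "efficacy_gain_formula",
    "base_efficacy",
    "reduce_params",
    "combined_efficacy",
    "benefit_threshold",
    "always_detrimental_by_y",
    "classify_regime",
    "monte_carlo_efficacy",
]

#: Slack accepted when validating probabilities, to absorb float round-off
#: from upstream arithmetic (e.g. 1.0000000001); values inside the slack are
#: clamped onto [0, 1].
VALIDATION_TOL = 1e-9

#: Absolute tolerance below which an efficacy difference counts as a tie
#: (no benefit) rather than numerical noise counted as benefit.
COMPARISON_TOL = 1e-12

#: Default seed for the stochastic oracle when none is supplied.
DEFAULT_SEED = 20260101


class DegenerateParameterError(ValueError):
    """The benefit threshold is undefined because x*y*z*alpha == 0.

    The threshold formula divides by y, z, x*z and alpha.  Use
    :func:`classify_regime`, which resolves these cases from the analytic
    sign of the efficacy gain instead.
    """


def _unit(value: float, name: str) -> float:
    v = float(value)
    if not math.isfinite(v) or v < -VALIDATION_TOL or v > 1.0 + VALIDATION_TOL:
        raise ValueError(f"{name} must be a fraction in [0, 1]; got {value!r}")
    return min(max(v, 0.0), 1.0)


@dataclass(frozen=True)
class CloneParams:
    """Per-clone inhibition probabilities.

    Parameters
    ----------
    x : float
        Efficacy of ara-C on the clone absent SAMHD1 interference.
    y : float
        Direct SAMHD1 tumour-suppressor efficacy on the clone.
    z : float
        Fractional reduction of ara-C efficacy caused by SAMHD1's
        ara-CTPase activity.
    """

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", _unit(self.x, "x"))
        object.__setattr__(self, "y", _unit(self.y, "y"))
        object.__setattr__(self, "z", _unit(self.z, "z"))


@dataclass(frozen=True)
class DrugSpec:
    """SAMHD1 inhibitor: efficacy ``d`` (= d_z, against the ara-CTPase
    function) and specificity ratio ``alpha`` = d_y / d_z.

    ``alpha = 1`` is a symmetric inhibitor hitting both SAMHD1 functions
    equally; ``alpha -> 0`` is fully ara-CTPase-specific.  The implied
    tumour-suppressor-side efficacy is ``d_y = alpha * d``.
    """

    d: float
    alpha: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "d", _unit(self.d, "d"))
        object.__setattr__(self, "alpha", _unit(self.alpha, "alpha"))

    @property
    def d_z(self) -> float:
        return self.d

    @property
    def d_y(self) -> float:
        return self.alpha * self.d

    @classmethod
    def from_function_efficacies(cls, d_y: float, d_z: float) -> "DrugSpec":
        """Build from the two per-function efficacies (d_y <= d_z required)."""
        d_z = _unit(d_z, "d_z")
        d_y = _unit(d_y, "d_y")
        if d_z == 0.0:
            if d_y > 0.0:
                raise ValueError("d_y > 0 with d_z = 0 has no alpha = d_y/d_z in [0, 1]")
            return cls(d=0.0, alpha=1.0)
        alpha = d_y / d_z
        if alpha > 1.0 + VALIDATION_TOL:
            raise ValueError(f"d_y/d_z = {alpha} exceeds 1; alpha must lie in [0, 1]")
        return cls(d=d_z, alpha=min(alpha, 1.0))


@dataclass(frozen=True)
class ReducedParams:
    """Drug-rescaled parameters and resulting ara-C efficacies.

    ``x_red`` is the ara-C efficacy under untreated SAMHD1 interference,
    ``x_imp`` the improved efficacy once the inhibitor has reduced z.
    """

    x_red: float
    y_red: float
    z_red: float
    x_imp: float


class Regime(enum.Enum):
    """Benefit regime of adding the SAMHD1 inhibitor, over d in (0, 1]."""

    ALWAYS_BENEFICIAL = "always_beneficial"
    NEVER_BENEFICIAL = "never_beneficial"
    CONDITIONAL = "conditional"
    NEUTRAL = "neutral"


@dataclass(frozen=True)
class RegimeClassification:
    """Regime plus the critical drug efficacy.

    ``threshold`` is the interior critical d where defined, ``-inf`` /
    ``+inf`` sentinels for the degenerate always/never branches, and NaN for
    NEUTRAL (the drug has identically zero effect).
    """

    regime: Regime
    threshold: float

    @property
    def beneficial_for(self) -> str:
        if self.regime is Regime.ALWAYS_BENEFICIAL:
            return "all d > 0"
        if self.regime is Regime.NEVER_BENEFICIAL:
            return "no d in (0, 1]"
        if self.regime is Regime.CONDITIONAL:
            return f"d > {self.threshold:.6g}"
        return "no effect"


class MonteCarloResult(NamedTuple):
    efficacy: float
    se: float


# ---------------------------------------------------------------------------
# Array kernels: plain functions of (x, y, z, d, alpha), broadcastable.
# ---------------------------------------------------------------------------

def efficacy_formula(x, y, z):
    """Base cycle efficacy e = y + x - x*z - y*x + x*y*z (vectorised)."""
    x, y, z = np.asarray(x, float), np.asarray(y, float), np.asarray(z, float)
    return y + x - x * z - y * x + x * y * z


def combined_formula(x, y, z, d, alpha=1.0):
    """Cycle efficacy with the inhibitor: base formula at the reduced
    values y_red = (1 - alpha*d)*y, z_red = (1 - d)*z (vectorised)."""
    d = np.asarray(d, float)
    alpha = np.asarray(alpha, float)
    y_red = (1.0 - alpha * d) * np.asarray(y, float)
    z_red = (1.0 - d) * np.asarray(z, float)
    return efficacy_formula(x, y_red, z_red)


def threshold_formula(x, y, z, alpha=1.0):
    """Critical inhibitor efficacy d* (vectorised; no domain checks)."""
    x, y, z = np.asarray(x, float), np.asarray(y, float), np.asarray(z, float)
    alpha = np.asarray(alpha, float)
    return (1.0 + alpha) / alpha - 1.0 / z - 1.0 / (alpha * y) + 1.0 / (x * z)


def efficacy_gain_formula(x, y, z, d, alpha=1.0):
    """Benefit of the inhibitor, e(d) - e(0), in the factorised form
    d * [x*z + a*x*y - a*y - (1+a)*x*y*z + a*x*y*z*d] (vectorised)."""
    x, y, z = np.asarray(x, float), np.asarray(y, float), np.asarray(z, float)
    d, a = np.asarray(d, float), np.asarray(alpha, float)
    return d * (x * z + a * x * y - a * y - (1.0 + a) * x * y * z + a * x * y * z * d)


# ---------------------------------------------------------------------------
# Typed operations.
# ---------------------------------------------------------------------------

def base_efficacy(params: CloneParams) -> float:
    """Treatment-cycle efficacy of ara-C under SAMHD1, without inhibitor."""
    return float(efficacy_formula(params.x, params.y, params.z))


def reduce_params(params: CloneParams, drug: DrugSpec) -> ReducedParams:
    """Rescale (y, z) by the inhibitor and derive the ara-C efficacies."""
    y_red = (1.0 - drug.alpha * drug.d) * params.y
    z_red = (1.0 - drug.d) * params.z
    return ReducedParams(
        x_red=(1.0 - params.z) * params.x,
        y_red=y_red,
        z_red=z_red,
        x_imp=(1.0 - z_red) * params.x,
    )


def combined_efficacy(params: CloneParams, drug: DrugSpec) -> float:
    """Cycle efficacy of ara-C plus the SAMHD1 inhibitor."""
    return float(combined_formula(params.x, params.y, params.z, drug.d, drug.alpha))


def benefit_threshold(params: CloneParams, alpha: float = 1.0) -> float:
    """Critical inhibitor efficacy d* above which adding it is beneficial.

    Only defined for strictly positive x, y, z, alpha; raises
    :class:`DegenerateParameterError` otherwise (use :func:`classify_regime`,
    which resolves those cases analytically).  The returned value may lie
    outside [0, 1]: <= 0 means always beneficial, >= 1 never beneficial on
    the physical range of d.
    """
    alpha = _unit(alpha, "alpha")
    if params.x * params.y * params.z * alpha == 0.0:
        raise DegenerateParameterError(
            f"threshold undefined for x={params.x}, y={params.y}, "
            f"z={params.z}, alpha={alpha}; use classify_regime"
        )
    return float(threshold_formula(params.x, params.y, params.z, alpha))


def always_detrimental_by_y(y: float, d: float, alpha: float = 1.0) -> bool:
    """True when the tumour-suppressor effect alone makes the inhibitor
    detrimental regardless of x and z: y > 1 / (1 + alpha - alpha*d)."""
    y = _unit(y, "y")
    d = _unit(d, "d")
    alpha = _unit(alpha, "alpha")
    return y > 1.0 / (1.0 + alpha - alpha * d)


def classify_regime(params: CloneParams, alpha: float = 1.0) -> RegimeClassification:
    """Classify the inhibitor's benefit regime over d in (0, 1].

    The efficacy gain factorises as ``delta(d) = d * g(d)`` with
    ``g(d) = x*z + a*x*y - a*y - (1+a)*x*y*z + a*x*y*z*d`` linear and
    non-decreasing in d.  For interior parameters the sign flip of g is the
    threshold formula; when the slope ``a*x*y*z`` vanishes g is constant and
    its sign settles the regime outright.  Ties (|g| below the comparison
    tolerance) count as no benefit; a gain identically zero is NEUTRAL.
    """
    x, y, z = params.x, params.y, params.z
    alpha = _unit(alpha, "alpha")
    slope = alpha * x * y * z
    g0 = x * z + alpha * x * y - alpha * y - (1.0 + alpha) * x * y * z
    if slope <= COMPARISON_TOL:
        if abs(g0) <= COMPARISON_TOL:
            return RegimeClassification(Regime.NEUTRAL, math.nan)
        if g0 > 0.0:
            return RegimeClassification(Regime.ALWAYS_BENEFICIAL, -math.inf)
        return RegimeClassification(Regime.NEVER_BENEFICIAL, math.inf)
    t = float(threshold_formula(x, y, z, alpha))
    if t <= 0.0:
        return RegimeClassification(Regime.ALWAYS_BENEFICIAL, t)
    if t >= 1.0:
        return RegimeClassification(Regime.NEVER_BENEFICIAL, t)
    return RegimeClassification(Regime.CONDITIONAL, t)


def monte_carlo_efficacy(
    params: CloneParams,
    drug: DrugSpec,
    n_cells: int,
    seed: int | None = None,
) -> MonteCarloResult:
    """Stochastic oracle for the two-route survival model.

    Each of ``n_cells`` is independently killed by the ara-C route with
    probability ``x_imp`` and by the direct SAMHD1 route with probability
    ``y_red``; the killed fraction estimates the combined efficacy.  Returns
    the estimate with its binomial standard error; deterministic given the
    seed (default :data:`DEFAULT_SEED`).
    """
    if n_cells < 1:
        raise ValueError(f"n_cells must be >= 1; got {n_cells}")
    red = reduce_params(params, drug)
    rng = np.random.default_rng(DEFAULT_SEED if seed is None else seed)
    killed = (rng.random(n_cells) < red.x_imp) | (rng.random(n_cells) < red.y_red)
    frac = float(killed.mean())
    se = math.sqrt(frac * (1.0 - frac) / n_cells)
    return MonteCarloResult(frac, se)
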
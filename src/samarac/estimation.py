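"""Estimation of x, y, z from cell-viability tables, with uncertainty.

The experimental design: THP-1 AML cells are exposed to increasing ara-C
concentrations under conditions that manipulate SAMHD1 levels with
Vpx-carrying virus-like particles (VLPs).  Undiluted Vpx ("VPX:100")
degrades SAMHD1 to negligible levels, giving a SAMHD1-null reference where
the cycle efficacy reduces to e = x, so x(c) = 1 - viability.  Empty-VLP
("EMPTY_VLP:<level>") and untreated ("NO_VLP") controls keep endogenous
SAMHD1.  At zero ara-C (x = 0) the efficacy reduces to e = y, so y is the
relative viability deficit of a condition versus the best-surviving
condition group.  With x and y in hand, z at each concentration inverts the
base efficacy formula:

    z = (1 - v - y - x + x*y) / (x*y - x).

Uncertainty: replicate viabilities at each concentration give a coefficient
of variation CV = SD/mean; averaging per-concentration CVs yields one
relative error scale sigma_v = CV * v, which first-order (delta-method)
propagation carries through the estimators assuming uncorrelated errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import efficacy_formula

__all__ = [
    "REQUIRED_COLUMNS",
    "NULL_CONDITION",
    "CONTROL_CONDITIONS",
    "ClampedEstimateWarning",
    "MissingConditionError",
    "InsufficientReplicatesError",
    "ConcentrationMismatchError",
    "ParamEstimate",
    "validate_viability",
    "estimate_x",
    "estimate_y",
    "endogenous_y",
    "estimate_z",
    "estimate_z_raw",
    "z_sd_propagated",
    "viability_cv",
    "build_dose_response",
]

REQUIRED_COLUMNS = ("concentration_uM", "condition", "replicate", "viability")

#: Condition label for the SAMHD1-null reference (undiluted Vpx VLPs).
NULL_CONDITION = "VPX:100"

#: Prefixes of conditions retaining endogenous SAMHD1 (wild-type controls).
CONTROL_CONDITIONS = ("EMPTY_VLP", "NO_VLP")


class ClampedEstimateWarning(UserWarning):
    """An estimate fell outside [0, 1] and was clamped (flagged, not silent)."""


class MissingConditionError(ValueError):
    """The table lacks records for a required condition."""


class InsufficientReplicatesError(ValueError):
    """Fewer than two samples at a concentration: no spread to measure."""


class ConcentrationMismatchError(ValueError):
    """Condition series do not share a common concentration grid."""


@dataclass(frozen=True)
class ParamEstimate:
    """A point estimate with its standard deviation and provenance.

    ``raw`` keeps the unclamped value when clamping occurred; ``clamped``
    flags it so no truncation is silent.
    """

    value: float
    sd: float
    method: str
    n: int
    raw: float | None = None
    clamped: bool = False

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def _is_control(condition: pd.Series) -> pd.Series:
    pattern = "|".join(f"^{c}" for c in CONTROL_CONDITIONS)
    return condition.str.match(pattern)


def validate_viability(table: pd.DataFrame, percent: bool = False) -> pd.DataFrame:
    """Check schema and normalise viability to a fraction in [0, 1]."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"viability table lacks required columns: {missing}")
    out = table.copy()
    out["condition"] = out["condition"].astype(str)
    out["viability"] = out["viability"].astype(float)
    if percent:
        out["viability"] = out["viability"] / 100.0
    if (out["viability"] < -1e-9).any() or (out["viability"] > 1 + 1e-9).any():
        bad = out.loc[(out["viability"] < -1e-9) | (out["viability"] > 1 + 1e-9)]
        raise ValueError(
            f"viability outside [0, 1] after normalisation at rows {list(bad.index)}"
        )
    out["viability"] = out["viability"].clip(0.0, 1.0)
    if (out["concentration_uM"].astype(float) < 0).any():
        raise ValueError("concentrations must be >= 0")
    return out


def estimate_x(
    table: pd.DataFrame,
    null_condition: str = NULL_CONDITION,
    sd_method: str = "replicates",
    cv: float | None = None,
) -> pd.DataFrame:
    """ara-C efficacy x per concentration from the SAMHD1-null condition.

    x(c) = 1 - mean viability at c.  ``sd_method='replicates'`` takes the
    standard error of the replicate mean; ``'cv'`` uses the global relative
    error model sigma = cv * v (requires ``cv``).

    Returns a DataFrame with columns concentration_uM, x, x_sd, n sorted by
    concentration.
    """
    table = validate_viability(table)
    null = table[table["condition"] == null_condition]
    if null.empty:
        raise MissingConditionError(
            f"no records for SAMHD1-null condition {null_condition!r}"
        )
    rows = []
    for conc, grp in null.groupby("concentration_uM"):
        v = grp["viability"].to_numpy()
        mean_v = v.mean()
        if sd_method == "replicates":
            sd = v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0
        elif sd_method == "cv":
            if cv is None:
                raise ValueError("sd_method='cv' requires the cv argument")
            sd = cv * mean_v
        else:
            raise ValueError(f"unknown sd_method {sd_method!r}")
        rows.append(
            {"concentration_uM": float(conc), "x": 1.0 - mean_v, "x_sd": float(sd),
             "n": len(v)}
        )
    return pd.DataFrame(rows).sort_values("concentration_uM", ignore_index=True)


def estimate_y(
    table: pd.DataFrame,
    sd_method: str = "sem",
) -> pd.DataFrame:
    """SAMHD1 tumour-suppressor efficacy y per condition, at zero ara-C.

    At x = 0 the cycle efficacy reduces to e = y, so each condition's y is
    its viability deficit relative to the best-surviving condition group:
    y = 1 - mean(v_condition) / mean(v_reference).  Working on the ratio
    makes the estimate independent of the assay's absolute scale.  The
    endogenous-SAMHD1 value comes from the pooled wild-type controls
    (empty-VLP and no-VLP); Vpx-degraded conditions typically sit at the
    reference itself, hence y = 0.

    ``sd_method``: 'sem' (standard error of the condition mean, default) or
    'sd' (single-measurement standard deviation); both propagate through the
    ratio assuming independent errors.
    """
    table = validate_viability(table)
    zero = table[table["concentration_uM"].astype(float) == 0.0]
    if zero.empty:
        raise MissingConditionError("no zero-ara-C records to estimate y from")
    is_ctrl = _is_control(zero["condition"])
    if not is_ctrl.any():
        raise MissingConditionError(
            f"no control records (conditions {CONTROL_CONDITIONS}) at zero ara-C"
        )

    def spread(v: np.ndarray) -> float:
        if len(v) < 2:
            return 0.0
        sd = v.std(ddof=1)
        return float(sd / np.sqrt(len(v))) if sd_method == "sem" else float(sd)

    groups: dict[str, np.ndarray] = {
        str(cond): grp["viability"].to_numpy() for cond, grp in zero.groupby("condition")
    }
    controls = zero.loc[is_ctrl, "viability"].to_numpy()
    pooled = {"ENDOGENOUS": controls}
    for cond, v in groups.items():
        if not cond.startswith(CONTROL_CONDITIONS):
            pooled[cond] = v
    means = {c: v.mean() for c, v in pooled.items()}
    ref_cond = max(means, key=means.get)
    ref_v = pooled[ref_cond]
    m_ref, s_ref = ref_v.mean(), spread(ref_v)
    rows = []
    for cond, v in pooled.items():
        m, s = v.mean(), spread(v)
        y_val = 1.0 - m / m_ref
        # ratio delta method: var(m/m_ref) = (s/m_ref)^2 + (m*s_ref/m_ref^2)^2
        sd = float(np.hypot(s / m_ref, m * s_ref / m_ref**2))
        raw, clamped = y_val, False
        if y_val < 0.0 or y_val > 1.0:
            clamped = True
            warnings.warn(
                f"y estimate {y_val:.6g} for condition {cond!r} outside [0, 1]; clamped",
                ClampedEstimateWarning,
                stacklevel=2,
            )
            y_val = min(max(y_val, 0.0), 1.0)
        rows.append(
            {"condition": cond, "y": y_val, "y_sd": sd, "n": len(v),
             "raw": raw, "clamped": clamped}
        )
    return pd.DataFrame(rows)


def endogenous_y(table: pd.DataFrame, sd_method: str = "sem") -> ParamEstimate:
    """y at endogenous SAMHD1 levels (pooled wild-type controls)."""
    df = estimate_y(table, sd_method=sd_method)
    row = df[df["condition"] == "ENDOGENOUS"].iloc[0]
    return ParamEstimate(
        value=float(row["y"]), sd=float(row["y_sd"]),
        method=f"control-ratio/{sd_method}", n=int(row["n"]),
        raw=float(row["raw"]), clamped=bool(row["clamped"]),
    )


def estimate_z_raw(viability: float, x: float, y: float) -> float:
    """Invert the base efficacy formula for z, without range clamping."""
    if x == 0.0 or y == 1.0:
        raise ZeroDivisionError(
            f"z is undefined at x={x}, y={y}: denominator x*(y-1) vanishes"
        )
    return (1.0 - viability - y - x + x * y) / (x * y - x)


def estimate_z(viability: float, x: float, y: float) -> float:
    """SAMHD1 ara-CTPase efficacy z from a viability measurement.

    Exact inverse of the base efficacy formula: feeding
    v = 1 - e(x, y, z) returns z.  Measurement noise can push the inversion
    slightly outside [0, 1]; such values are clamped with a
    :class:`ClampedEstimateWarning` (z = 1 "up to experimental
    uncertainty"), never silently.
    """
    z = estimate_z_raw(viability, x, y)
    if z < 0.0 or z > 1.0:
        warnings.warn(
            f"z estimate {z:.6g} outside [0, 1]; clamped", ClampedEstimateWarning,
            stacklevel=2,
        )
        z = min(max(z, 0.0), 1.0)
    return z


def z_sd_propagated(
    viability: float, x: float, y: float,
    sd_v: float, sd_x: float = 0.0, sd_y: float = 0.0,
) -> float:
    """Delta-method standard deviation of the z estimate.

    First-order propagation through z(v, x, y) with independent errors:
    sigma_z^2 = (dz/dv)^2 sd_v^2 + (dz/dx)^2 sd_x^2 + (dz/dy)^2 sd_y^2,
    using the analytic partials of the inversion formula
    (dz/dv = 1/(x(1-y)); the others follow from the quotient rule).
    """
    if x == 0.0 or y == 1.0:
        raise ZeroDivisionError("partials diverge at x=0 or y=1")
    num = 1.0 - viability - y - x + x * y
    den = x * (y - 1.0)
    dz_dv = -1.0 / den
    dz_dx = ((y - 1.0) * den - num * (y - 1.0)) / den**2
    dz_dy = ((x - 1.0) * den - num * x) / den**2
    return float(np.sqrt((dz_dv * sd_v) ** 2 + (dz_dx * sd_x) ** 2 + (dz_dy * sd_y) ** 2))


def viability_cv(
    table: pd.DataFrame,
    conditions: tuple[str, ...] | list[str] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Per-concentration coefficients of variation and their mean.

    CV = sample SD / mean (ddof=1) across the samples of the named
    conditions at each concentration; the summary is the arithmetic mean of
    the per-concentration CVs.  Defaults to the wild-type control
    conditions, mirroring how the assay's noise scale is calibrated.
    """
    table = validate_viability(table)
    if conditions is None:
        sel = table[_is_control(table["condition"])]
    else:
        sel = table[table["condition"].isin(list(conditions))]
    if sel.empty:
        raise MissingConditionError("no records match the requested conditions")
    rows = []
    for conc, grp in sel.groupby("concentration_uM"):
        v = grp["viability"].to_numpy()
        if len(v) < 2:
            raise InsufficientReplicatesError(
                f"need >= 2 samples at concentration {conc}; got {len(v)}"
            )
        mean = v.mean()
        cv = float(v.std(ddof=1) / mean) if mean > 0 else np.nan
        rows.append({"concentration_uM": float(conc), "cv": cv, "n": len(v)})
    df = pd.DataFrame(rows).sort_values("concentration_uM", ignore_index=True)
    return df, float(df["cv"].mean())


def build_dose_response(
    table: pd.DataFrame,
    null_condition: str = NULL_CONDITION,
    y: ParamEstimate | None = None,
    interpolate: bool = False,
) -> pd.DataFrame:
    """Per-concentration (x, z) estimates with propagated uncertainties.

    x comes from the SAMHD1-null series, z from inverting the endogenous
    (wild-type control) series at the same concentrations using the
    endogenous y (estimated from the table's zero-ara-C records unless
    supplied).  sigma_v per series uses the table's mean control CV.
    Concentrations present in only one series raise
    :class:`ConcentrationMismatchError` unless ``interpolate`` is set, in
    which case the endogenous viability is piecewise-linearly interpolated
    onto the null grid.

    Returns columns: concentration_uM, x, x_sd, z_raw, z, z_sd, z_clamped.
    """
    table = validate_viability(table)
    y_est = endogenous_y(table) if y is None else y
    x_tab = estimate_x(table, null_condition=null_condition)
    _, mean_cv = viability_cv(table)

    ctrl = table[_is_control(table["condition"])]
    endo = (
        ctrl.groupby("concentration_uM")["viability"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "v_endo", "count": "n_endo"})
    )
    x_conc = x_tab["concentration_uM"].to_numpy()
    e_conc = endo["concentration_uM"].to_numpy()
    if not interpolate:
        missing = sorted(set(np.round(x_conc, 12)) ^ set(np.round(e_conc, 12)))
        if missing:
            raise ConcentrationMismatchError(
                f"null and endogenous series disagree on concentrations: {missing} "
                "(pass interpolate=True to bridge)"
            )
        v_endo = endo.set_index("concentration_uM").loc[x_conc, "v_endo"].to_numpy()
    else:
        order = np.argsort(e_conc)
        v_endo = np.interp(x_conc, e_conc[order], endo["v_endo"].to_numpy()[order])

    rows = []
    for conc, xv, x_sd, v in zip(x_conc, x_tab["x"], x_tab["x_sd"], v_endo):
        if xv == 0.0:
            # zero ara-C (or fully protected): z carries no information
            rows.append(
                {"concentration_uM": conc, "x": xv, "x_sd": x_sd,
                 "z_raw": np.nan, "z": np.nan, "z_sd": np.nan, "z_clamped": False}
            )
            continue
        z_raw = estimate_z_raw(v, xv, y_est.value)
        clamped = not (0.0 <= z_raw <= 1.0)
        if clamped:
            warnings.warn(
                f"z estimate {z_raw:.6g} at {conc} uM outside [0, 1]; clamped",
                ClampedEstimateWarning,
                stacklevel=2,
            )
        z_sd = z_sd_propagated(
            v, xv, y_est.value, sd_v=mean_cv * v, sd_x=x_sd, sd_y=y_est.sd
        )
        rows.append(
            {"concentration_uM": conc, "x": xv, "x_sd": x_sd, "z_raw": z_raw,
             "z": min(max(z_raw, 0.0), 1.0), "z_sd": z_sd, "z_clamped": clamped}
        )
    return pd.DataFrame(rows)


def expected_viability(x: float, y: float, z: float) -> float:
    """Model viability 1 - e(x, y, z); the forward map the estimators invert."""
    return 1.0 - float(efficacy_formula(x, y, z))
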
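"""File formats: clone-configuration and regimen JSON, viability/trace CSV.

Clone configurations are schema-versioned JSON documents::

    {
      "schema_version": 1,
      "drug": {"d": 0.5, "alpha": 1.0},
      "clones": [
        {"id": "C1", "fraction": 0.5, "x": 0.8, "y": 0.3, "z": 0.7,
         "d": null, "weight": null,
         "doses": {"low": {"x": 0.4, "z": 0.9}}}
      ]
    }

Regimen plans are ordered cycle lists::

    {"cycles": [{"drug_on": false, "d": 0.0, "alpha": 1.0, "dose_label": null}]}

Validation is strict (pydantic models, field locations in error messages);
fraction sums are only auto-normalised on explicit request.  Tabular data
(viability measurements, regimen traces, dose-response tables) travel as
comma-separated UTF-8 CSV with a header row and '.' decimals.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
from pydantic import BaseModel, Field, ValidationError

from .clonal import Clone, ClonePopulation, CyclePlan, RegimenTrace
from .estimation import validate_viability
from .model import CloneParams, DrugSpec

__all__ = [
    "ConfigError",
    "load_clone_config",
    "save_clone_config",
    "load_regimen",
    "save_regimen",
    "read_viability_csv",
    "write_trace_csv",
]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """A configuration file failed validation (message carries the location)."""


class _DoseModel(BaseModel, extra="forbid"):
    x: float = Field(ge=0.0, le=1.0)
    z: float = Field(ge=0.0, le=1.0)


class _CloneModel(BaseModel, extra="forbid"):
    id: str
    fraction: float = Field(ge=0.0, le=1.0)
    x: float = Field(ge=0.0, le=1.0)
    y: float = Field(ge=0.0, le=1.0)
    z: float = Field(ge=0.0, le=1.0)
    d: float | None = Field(default=None, ge=0.0, le=1.0)
    weight: float | None = Field(default=None, ge=0.0, le=1.0)
    doses: dict[str, _DoseModel] | None = None


class _DrugModel(BaseModel, extra="forbid"):
    d: float = Field(default=0.0, ge=0.0, le=1.0)
    alpha: float = Field(default=1.0, ge=0.0, le=1.0)


class _CloneConfigModel(BaseModel, extra="forbid"):
    schema_version: int = SCHEMA_VERSION
    drug: _DrugModel = _DrugModel()
    clones: list[_CloneModel] = Field(min_length=1)


class _CycleModel(BaseModel, extra="forbid"):
    drug_on: bool = False
    d: float = Field(default=0.0, ge=0.0, le=1.0)
    alpha: float = Field(default=1.0, ge=0.0, le=1.0)
    dose_label: str | None = None


class _RegimenModel(BaseModel, extra="forbid"):
    cycles: list[_CycleModel] = Field(min_length=1)


def _format_validation_error(err: ValidationError, path: Path) -> str:
    lines = []
    for e in err.errors():
        loc = ".".join(str(p) for p in e["loc"]) or "<root>"
        lines.append(f"{path}: {loc}: {e['msg']}")
    return "; ".join(lines)


def _load_json(path: str | Path) -> tuple[Path, object]:
    path = Path(path)
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except FileNotFoundError:
        raise ConfigError(f"{path}: file not found") from None
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{path}: invalid JSON: {exc}") from None
    return path, payload


def load_clone_config(
    path: str | Path, normalise: bool = False
) -> tuple[ClonePopulation, DrugSpec]:
    """Read and validate a clone-configuration JSON file.

    Fraction sums that deviate from 1 raise unless ``normalise`` is set, in
    which case the fractions are rescaled proportionally.
    """
    path, payload = _load_json(path)
    try:
        cfg = _CloneConfigModel.model_validate(payload)
    except ValidationError as exc:
        raise ConfigError(_format_validation_error(exc, path)) from None
    if cfg.schema_version != SCHEMA_VERSION:
        raise ConfigError(
            f"{path}: schema_version: unsupported version {cfg.schema_version} "
            f"(expected {SCHEMA_VERSION})"
        )
    ids = [c.id for c in cfg.clones]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ConfigError(f"{path}: clones: duplicate ids {dupes}")
    fractions = [c.fraction for c in cfg.clones]
    total = sum(fractions)
    if abs(total - 1.0) > 1e-9:
        if not normalise:
            raise ConfigError(
                f"{path}: clones: fractions sum to {total:.12g}, expected 1 "
                "(pass normalise to rescale)"
            )
        if total <= 0:
            raise ConfigError(f"{path}: clones: fractions sum to {total:.12g}")
        fractions = [f / total for f in fractions]
    try:
        clones = tuple(
            Clone(
                id=c.id,
                fraction=f,
                params=CloneParams(x=c.x, y=c.y, z=c.z),
                drug_efficacy_override=c.d,
                priority_weight=c.weight,
                dose_params=(
                    {label: (dm.x, dm.z) for label, dm in c.doses.items()}
                    if c.doses
                    else None
                ),
            )
            for c, f in zip(cfg.clones, fractions)
        )
        population = ClonePopulation(clones)
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from None
    return population, DrugSpec(d=cfg.drug.d, alpha=cfg.drug.alpha)


def _fmt(v: float) -> float:
    # 12 significant digits: stable round-trip text without float noise
    return float(f"{v:.12g}")


def save_clone_config(
    pop: ClonePopulation, drug: DrugSpec, path: str | Path
) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "drug": {"d": _fmt(drug.d), "alpha": _fmt(drug.alpha)},
        "clones": [
            {
                "id": c.id,
                "fraction": _fmt(c.fraction),
                "x": _fmt(c.params.x),
                "y": _fmt(c.params.y),
                "z": _fmt(c.params.z),
                "d": None if c.drug_efficacy_override is None else _fmt(c.drug_efficacy_override),
                "weight": None if c.priority_weight is None else _fmt(c.priority_weight),
                "doses": (
                    None
                    if c.dose_params is None
                    else {
                        label: {"x": _fmt(x), "z": _fmt(z)}
                        for label, (x, z) in c.dose_params.items()
                    }
                ),
            }
            for c in pop.clones
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def load_regimen(
    path: str | Path, population: ClonePopulation | None = None
) -> list[CyclePlan]:
    """Read a regimen JSON file; dose labels are checked against the
    population's per-clone dose maps when one is supplied."""
    path, payload = _load_json(path)
    try:
        reg = _RegimenModel.model_validate(payload)
    except ValidationError as exc:
        raise ConfigError(_format_validation_error(exc, path)) from None
    plans = [
        CyclePlan(drug_on=c.drug_on, d=c.d, alpha=c.alpha, dose_label=c.dose_label)
        for c in reg.cycles
    ]
    if population is not None:
        for i, plan in enumerate(plans):
            if plan.dose_label is None:
                continue
            for clone in population.clones:
                if clone.dose_params is None or plan.dose_label not in clone.dose_params:
                    raise ConfigError(
                        f"{path}: cycles.{i}.dose_label: label {plan.dose_label!r} "
                        f"not defined for clone {clone.id!r}"
                    )
    return plans


def save_regimen(plans: Sequence[CyclePlan], path: str | Path) -> None:
    doc = {
        "cycles": [
            {"drug_on": p.drug_on, "d": _fmt(p.d), "alpha": _fmt(p.alpha),
             "dose_label": p.dose_label}
            for p in plans
        ]
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def read_viability_csv(path: str | Path, percent: bool = False) -> pd.DataFrame:
    """Read and validate a viability CSV (columns: concentration_uM,
    condition, replicate, viability, optional samhd1_relative).  With
    ``percent``, viabilities given on the 0-100 scale are divided by 100."""
    try:
        table = pd.read_csv(path)
    except FileNotFoundError:
        raise ConfigError(f"{path}: file not found") from None
    try:
        return validate_viability(table, percent=percent)
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from None


def write_trace_csv(trace: RegimenTrace, path: str | Path) -> None:
    trace.to_frame().to_csv(path, index=False)
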
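"""Oligoclonal efficacy aggregation and treatment-sequence simulation.

An oligoclonal AML is N clones with fractions f_i summing to 1, each with
its own (x_i, y_i, z_i).  A cycle's total efficacy is the mixture
e_total = sum f_i * e_i.  Because clones respond differently, treatment
exerts selection: after a cycle the fractions renormalise to

    f_i' = f_i * (1 - e_i) / (1 - e_total),

so clones hit harder than average shrink and resistant clones expand.  The
remaining burden after a sequence of cycles is the product of per-cycle
survival (1 - e_total), expressed relative to the untreated expectation.

Fraction updates are deterministic expected-value dynamics; stochastic
finite-population trajectories live in :mod:`samarac.synth`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .model import (
    COMPARISON_TOL,
    CloneParams,
    _unit,
    combined_formula,
)

__all__ = [
    "Clone",
    "ClonePopulation",
    "CyclePlan",
    "CycleRecord",
    "RegimenTrace",
    "EradicationError",
    "MissingWeightsError",
    "NonIdentifiableWarning",
    "DrugFit",
    "OptimizedCycle",
    "clone_efficacies",
    "total_efficacy",
    "weighted_efficacy",
    "update_fractions",
    "simulate_regimen",
    "min_cycles_until_drug_beneficial",
    "optimize_next_cycle",
    "fit_drug_efficacy",
]

FRACTION_SUM_TOL = 1e-9


class EradicationError(ValueError):
    """Total efficacy reached 1: no cells survive, fractions are undefined."""


class MissingWeightsError(ValueError):
    """A weighted objective was requested but priority weights are not set."""


class NonIdentifiableWarning(UserWarning):
    """The drug-efficacy fit residual is flat: d is not identifiable."""


@dataclass(frozen=True)
class Clone:
    """One AML clone: identity, population fraction, response parameters.

    ``drug_efficacy_override`` is a per-clone inhibitor efficacy d_i taking
    precedence over the cycle plan's d (e.g. efflux-pump expression);
    ``priority_weight`` w_i feeds the weighted clinical objective;
    ``dose_params`` maps a dose label to the (x, z) pair measured at that
    ara-C dose (y is dose-independent).
    """

    id: str
    fraction: float
    params: CloneParams
    drug_efficacy_override: float | None = None
    priority_weight: float | None = None
    dose_params: Mapping[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "fraction", _unit(self.fraction, "fraction"))
        if self.drug_efficacy_override is not None:
            object.__setattr__(
                self,
                "drug_efficacy_override",
                _unit(self.drug_efficacy_override, "drug_efficacy_override"),
            )
        if self.priority_weight is not None:
            object.__setattr__(
                self, "priority_weight", _unit(self.priority_weight, "priority_weight")
            )
        if self.dose_params is not None:
            checked = {
                str(label): (_unit(x, f"dose {label!r} x"), _unit(z, f"dose {label!r} z"))
                for label, (x, z) in dict(self.dose_params).items()
            }
            object.__setattr__(self, "dose_params", checked)

    def params_at(self, dose_label: str | None) -> CloneParams:
        """Clone parameters at a named ara-C dose (default dose when None)."""
        if dose_label is None:
            return self.params
        if self.dose_params is None or dose_label not in self.dose_params:
            raise KeyError(f"clone {self.id!r} has no dose label {dose_label!r}")
        x, z = self.dose_params[dose_label]
        return CloneParams(x=x, y=self.params.y, z=z)


@dataclass(frozen=True)
class ClonePopulation:
    clones: tuple[Clone, ...]

    def __post_init__(self) -> None:
        clones = tuple(self.clones)
        object.__setattr__(self, "clones", clones)
        if not clones:
            raise ValueError("population must contain at least one clone")
        ids = [c.id for c in clones]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate clone ids: {ids}")
        total = sum(c.fraction for c in clones)
        if abs(total - 1.0) > FRACTION_SUM_TOL:
            raise ValueError(f"clone fractions sum to {total!r}, expected 1")
        weights = [c.priority_weight for c in clones]
        if any(w is not None for w in weights):
            if any(w is None for w in weights):
                raise MissingWeightsError(
                    "priority weights must be set for all clones or none"
                )
            wsum = sum(weights)  # type: ignore[arg-type]
            if abs(wsum - 1.0) > FRACTION_SUM_TOL:
                raise ValueError(f"priority weights sum to {wsum!r}, expected 1")

    def __len__(self) -> int:
        return len(self.clones)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.clones)

    @property
    def fractions(self) -> np.ndarray:
        return np.array([c.fraction for c in self.clones])

    @property
    def weights(self) -> np.ndarray:
        ws = [c.priority_weight for c in self.clones]
        if any(w is None for w in ws):
            raise MissingWeightsError("priority weights are not set on this population")
        return np.array(ws, dtype=float)

    def with_fractions(self, fractions: Sequence[float]) -> "ClonePopulation":
        if len(fractions) != len(self.clones):
            raise ValueError("fraction vector length does not match population")
        return ClonePopulation(
            tuple(replace(c, fraction=float(f)) for c, f in zip(self.clones, fractions))
        )

    @classmethod
    def from_params(
        cls,
        params: Sequence[CloneParams],
        fractions: Sequence[float] | None = None,
        ids: Sequence[str] | None = None,
    ) -> "ClonePopulation":
        """Convenience constructor from bare parameter triples."""
        n = len(params)
        if fractions is None:
            fractions = [1.0 / n] * n
        if ids is None:
            ids = [f"C{i + 1}" for i in range(n)]
        return cls(
            tuple(
                Clone(id=str(i), fraction=float(f), params=p)
                for i, f, p in zip(ids, fractions, params)
            )
        )


@dataclass(frozen=True)
class CyclePlan:
    """One treatment cycle: ara-C always, the SAMHD1 inhibitor optionally.

    ``d`` is used only when ``drug_on`` (and is overridden per clone by
    ``Clone.drug_efficacy_override``); ``dose_label`` selects per-clone
    (x, z) parameter sets measured at a particular ara-C dose.
    """

    drug_on: bool = False
    d: float = 0.0
    alpha: float = 1.0
    dose_label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "d", _unit(self.d, "d"))
        object.__setattr__(self, "alpha", _unit(self.alpha, "alpha"))


@dataclass(frozen=True)
class CycleRecord:
    cycle: int
    fractions_before: np.ndarray
    efficacies: np.ndarray
    e_total: float
    fractions_after: np.ndarray
    burden: float


@dataclass
class RegimenTrace:
    """Per-cycle record of a simulated regimen.

    ``burden`` after cycle k is prod_{j<=k} (1 - e_total_j): the surviving
    population relative to the untreated expectation.  ``eradicated`` marks
    a regimen cut short because e_total reached 1.
    """

    clone_ids: tuple[str, ...]
    records: list[CycleRecord] = field(default_factory=list)
    eradicated: bool = False

    @property
    def burden(self) -> float:
        return self.records[-1].burden if self.records else 1.0

    @property
    def final_fractions(self) -> np.ndarray:
        return self.records[-1].fractions_after

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format trace: one row per cycle per clone."""
        rows = []
        for rec in self.records:
            for i, cid in enumerate(self.clone_ids):
                rows.append(
                    {
                        "cycle": rec.cycle,
                        "clone_id": cid,
                        "fraction_before": rec.fractions_before[i],
                        "efficacy": rec.efficacies[i],
                        "fraction_after": rec.fractions_after[i],
                        "e_total": rec.e_total,
                        "burden": rec.burden,
                    }
                )
        return pd.DataFrame(rows)


def clone_efficacies(pop: ClonePopulation, plan: CyclePlan) -> np.ndarray:
    """Per-clone cycle efficacies e_i under the plan's drug settings."""
    es = np.empty(len(pop))
    for i, clone in enumerate(pop.clones):
        p = clone.params_at(plan.dose_label)
        if plan.drug_on:
            d = plan.d if clone.drug_efficacy_override is None else clone.drug_efficacy_override
        else:
            d = 0.0
        es[i] = combined_formula(p.x, p.y, p.z, d, plan.alpha)
    return es


def total_efficacy(pop: ClonePopulation, plan: CyclePlan) -> float:
    """Population efficacy e_total = sum f_i * e_i."""
    return float(pop.fractions @ clone_efficacies(pop, plan))


def weighted_efficacy(pop: ClonePopulation, plan: CyclePlan) -> float:
    """Clinician-weighted objective sum w_i * e_i (requires weights)."""
    return float(pop.weights @ clone_efficacies(pop, plan))


def update_fractions(pop: ClonePopulation, efficacies: Sequence[float]) -> ClonePopulation:
    """Post-cycle selection update f_i' = f_i (1 - e_i) / (1 - e_total)."""
    e = np.asarray(efficacies, dtype=float)
    if e.shape != (len(pop),):
        raise ValueError("efficacy vector length does not match population")
    f = pop.fractions
    e_total = float(f @ e)
    survival = 1.0 - e_total
    if survival <= COMPARISON_TOL:
        raise EradicationError(
            "total efficacy is 1 within tolerance; updated fractions are undefined"
        )
    new_f = f * (1.0 - e)
    # dividing by the realised sum equals /(1 - e_total) exactly in exact
    # arithmetic but keeps the fractions summing to 1 under float round-off
    return pop.with_fractions(new_f / new_f.sum())


def simulate_regimen(pop: ClonePopulation, plans: Sequence[CyclePlan]) -> RegimenTrace:
    """Run a sequence of cycles, updating fractions and compounding burden.

    On eradication (e_total = 1 within tolerance) the trace records a final
    cycle with burden 0 and stops; remaining plans are not executed.
    """
    if not plans:
        raise ValueError("regimen must contain at least one cycle")
    trace = RegimenTrace(clone_ids=pop.ids)
    burden = 1.0
    current = pop
    for k, plan in enumerate(plans, start=1):
        f_before = current.fractions
        es = clone_efficacies(current, plan)
        e_total = float(f_before @ es)
        try:
            current = update_fractions(current, es)
        except EradicationError:
            trace.records.append(
                CycleRecord(k, f_before, es, e_total, np.full_like(f_before, np.nan), 0.0)
            )
            trace.eradicated = True
            return trace
        burden *= 1.0 - e_total
        trace.records.append(
            CycleRecord(k, f_before, es, e_total, current.fractions, burden)
        )
    return trace


def min_cycles_until_drug_beneficial(
    pop: ClonePopulation,
    d: float,
    alpha: float = 1.0,
    max_cycles: int = 25,
) -> int | None:
    """Smallest number k of ara-C-only cycles after which adding the
    inhibitor to the next cycle strictly raises that cycle's e_total.

    Myopic criterion: compares the (k+1)-th cycle's total efficacy with and
    without the drug at the fractions reached after k drug-free cycles.
    Returns None when no k <= max_cycles qualifies.  Eradication during the
    drug-free run raises :class:`EradicationError`.
    """
    if max_cycles < 1:
        raise ValueError("max_cycles must be >= 1")
    with_drug = CyclePlan(drug_on=True, d=d, alpha=alpha)
    without = CyclePlan(drug_on=False, alpha=alpha)
    current = pop
    for k in range(max_cycles + 1):
        if total_efficacy(current, with_drug) > total_efficacy(current, without) + COMPARISON_TOL:
            return k
        current = update_fractions(current, clone_efficacies(current, without))
    return None


@dataclass(frozen=True)
class OptimizedCycle:
    plan: CyclePlan
    score: float
    index: int


def optimize_next_cycle(
    pop: ClonePopulation,
    candidates: Sequence[CyclePlan],
    objective: str = "total",
) -> OptimizedCycle:
    """Greedy single-cycle optimisation: pick the candidate plan maximising
    the chosen objective at the current fractions (ties -> earliest)."""
    if not candidates:
        raise ValueError("candidates must be non-empty")
    if objective == "total":
        score = total_efficacy
    elif objective == "weighted":
        score = weighted_efficacy
    else:
        raise ValueError(f"objective must be 'total' or 'weighted'; got {objective!r}")
    best_i, best_s = 0, -np.inf
    for i, plan in enumerate(candidates):
        s = score(pop, plan)
        if s > best_s + COMPARISON_TOL:
            best_i, best_s = i, s
    return OptimizedCycle(plan=candidates[best_i], score=best_s, index=best_i)


@dataclass(frozen=True)
class DrugFit:
    d: float
    residual: float
    identifiable: bool


def fit_drug_efficacy(
    pre: ClonePopulation,
    post_fractions: Sequence[float],
    alpha: float = 1.0,
    grid_step: float = 1e-3,
) -> DrugFit:
    """Infer the inhibitor efficacy d from pre/post clonal fractions.

    Minimises over d in [0, 1] the sum of squared differences between the
    observed fraction ratios f_i'/f_i and the model prediction
    (1 - e_i(d)) / (1 - e_total(d)).  A dense grid scan locates the global
    basin; bounded 1-D refinement polishes it.  When the residual profile is
    flat (e.g. all clones identical) d is not identifiable: a
    :class:`NonIdentifiableWarning` is issued and the smallest d in the flat
    set returned.
    """
    if len(pre) < 2:
        raise ValueError("drug-efficacy fitting needs at least 2 clones")
    post = np.asarray(post_fractions, dtype=float)
    if post.shape != (len(pre),):
        raise ValueError("post-fraction vector length does not match population")
    if abs(post.sum() - 1.0) > 1e-6:
        raise ValueError(f"post fractions sum to {post.sum()!r}, expected 1")
    f = pre.fractions
    if np.any(f <= 0):
        raise ValueError("all pre-treatment fractions must be positive")
    observed = post / f

    def loss(d: float) -> float:
        plan = CyclePlan(drug_on=True, d=d, alpha=alpha)
        es = clone_efficacies(pre, plan)
        survival = 1.0 - float(f @ es)
        if survival <= COMPARISON_TOL:
            return np.inf
        predicted = (1.0 - es) / survival
        return float(np.sum((observed - predicted) ** 2))

    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    values = np.array([loss(d) for d in grid])
    finite = values[np.isfinite(values)]
    identifiable = bool(finite.size and (finite.max() - finite.min()) > 1e-12)
    if not identifiable:
        warnings.warn(
            "residual profile is flat over d: drug efficacy is not identifiable",
            NonIdentifiableWarning,
            stacklevel=2,
        )
        return DrugFit(d=float(grid[0]), residual=float(values[0]), identifiable=False)
    i = int(np.nanargmin(values))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi > lo:
        res = minimize_scalar(loss, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-10})
        if res.fun <= values[i]:
            return DrugFit(d=float(res.x), residual=float(res.fun), identifiable=True)
    return DrugFit(d=float(grid[i]), residual=float(values[i]), identifiable=True)
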
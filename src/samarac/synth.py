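"""Seeded generators of synthetic viability tables and clonal trajectories.

These emulate the structure of the calibration experiments (ara-C
dose-response viability assays under Vpx-controlled SAMHD1 levels) and of
serial clonal-fraction measurements across treatment cycles, so every
estimator and the simulator can be exercised end to end without external
data.  Viability noise is multiplicative Gaussian with a stated coefficient
of variation (default 9.4%, the assay's calibrated relative error),
truncated to [0, 1]; clone survival is binomial per cycle.  The generators
emulate the experiments' structure and noise scale only — they do not
reproduce any measured dataset, and real assays may violate the
independence and homogeneous-CV assumptions baked in here.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clonal import Clone, ClonePopulation, CyclePlan, clone_efficacies
from .estimation import CONTROL_CONDITIONS, NULL_CONDITION
from .model import CloneParams, efficacy_formula

__all__ = [
    "DEFAULT_CV",
    "gen_viability_table",
    "gen_clone_trajectory",
    "example_populations",
]

#: Calibrated relative error of replicate viability measurements.
DEFAULT_CV = 0.094


def gen_viability_table(
    concentrations: Sequence[float],
    x_of_c: Mapping[float, float] | Sequence[float],
    z_of_c: Mapping[float, float] | Sequence[float],
    y_endogenous: float,
    replicates: int = 6,
    cv: float = DEFAULT_CV,
    seed: int = 0,
    conditions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Synthetic dose-response viability table.

    For each concentration c the model viability is 1 - e with parameters
    depending on the condition: the SAMHD1-null condition (undiluted Vpx)
    has y = z = 0 so v = 1 - x(c); wild-type control conditions (empty-VLP,
    no-VLP) keep (x(c), y_endogenous, z(c)).  Each replicate is perturbed by
    multiplicative Gaussian noise of the given CV and truncated to [0, 1].
    Deterministic given the seed.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    concentrations = [float(c) for c in concentrations]
    if not isinstance(x_of_c, Mapping):
        x_of_c = dict(zip(concentrations, x_of_c))
    if not isinstance(z_of_c, Mapping):
        z_of_c = dict(zip(concentrations, z_of_c))
    if conditions is None:
        conditions = (NULL_CONDITION, f"{CONTROL_CONDITIONS[0]}:100", CONTROL_CONDITIONS[1])
    rng = np.random.default_rng(seed)
    rows = []
    for c in concentrations:
        x, z = float(x_of_c[c]), float(z_of_c[c])
        for cond in conditions:
            if cond == NULL_CONDITION:
                v_true = 1.0 - float(efficacy_formula(x, 0.0, 0.0))
            else:
                v_true = 1.0 - float(efficacy_formula(x, y_endogenous, z))
            noise = rng.normal(loc=1.0, scale=cv, size=replicates) if cv > 0 else np.ones(replicates)
            vs = np.clip(v_true * noise, 0.0, 1.0)
            for r, v in enumerate(vs, start=1):
                rows.append(
                    {"concentration_uM": c, "condition": cond, "replicate": r,
                     "viability": float(v)}
                )
    return pd.DataFrame(rows)


def gen_clone_trajectory(
    pop: ClonePopulation,
    plans: Sequence[CyclePlan],
    n_cells: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Stochastic finite-population analogue of the deterministic simulator.

    Starting from ``n_cells`` split by the initial fractions, each cycle
    draws per-clone survivor counts binomially with survival probability
    1 - e_i and re-derives observed fractions from the counts.  At large
    n_cells the observed fractions converge to the deterministic selection
    update.  Total extinction (all counts zero) is reported via a final row
    with NaN fractions.  Deterministic given the seed.

    Returns a tidy DataFrame: cycle, clone_id, count, fraction.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    counts = np.round(pop.fractions * n_cells).astype(np.int64)
    rows = [
        {"cycle": 0, "clone_id": cid, "count": int(k), "fraction": float(frac)}
        for cid, k, frac in zip(pop.ids, counts, pop.fractions)
    ]
    current = pop
    for cycle, plan in enumerate(plans, start=1):
        es = clone_efficacies(current, plan)
        counts = rng.binomial(counts, 1.0 - es)
        total = counts.sum()
        if total == 0:
            for cid, k in zip(pop.ids, counts):
                rows.append({"cycle": cycle, "clone_id": cid, "count": int(k),
                             "fraction": float("nan")})
            break
        fracs = counts / total
        for cid, k, frac in zip(pop.ids, counts, fracs):
            rows.append({"cycle": cycle, "clone_id": cid, "count": int(k),
                         "fraction": float(frac)})
        # survivors define the next cycle's composition
        current = current.with_fractions(fracs)
    return pd.DataFrame(rows)


def example_populations() -> dict[str, ClonePopulation]:
    """The worked-example clone configurations used throughout the docs.

    * ``mono_high_samhd1``: single clone (0.8, 0.1, 0.7) — high SAMHD1
      interference; inhibitor always beneficial.
    * ``mono_conditional``: single clone (0.7, 0.4, 0.5) — inhibitor
      beneficial only above d ~ 0.357.
    * ``two_clone_always_beneficial``: equal mix of (0.8, 0.3, 0.7) and
      (0.8, 0.1, 0.2); inhibitor helps both clones for any d.
    * ``two_clone_conditional``: equal mix of (0.9, 0.5, 0.6) and
      (0.8, 0.7, 0.7); per-clone critical efficacies ~0.19 and ~0.93.
    * ``three_clone_sequential``: equal thirds of (0.9, 0.6, 0.4),
      (0.8, 0.7, 0.5), (0.7, 0.8, 0.6); the sequential-treatment example
      where the inhibitor only becomes favourable after four ara-C-only
      cycles.
    """

    def pop(triples: Sequence[tuple[float, float, float]]) -> ClonePopulation:
        n = len(triples)
        return ClonePopulation(
            tuple(
                Clone(id=f"C{i + 1}", fraction=1.0 / n, params=CloneParams(*t))
                for i, t in enumerate(triples)
            )
        )

    return {
        "mono_high_samhd1": pop([(0.8, 0.1, 0.7)]),
        "mono_conditional": pop([(0.7, 0.4, 0.5)]),
        "two_clone_always_beneficial": pop([(0.8, 0.3, 0.7), (0.8, 0.1, 0.2)]),
        "two_clone_conditional": pop([(0.9, 0.5, 0.6), (0.8, 0.7, 0.7)]),
        "three_clone_sequential": pop(
            [(0.9, 0.6, 0.4), (0.8, 0.7, 0.5), (0.7, 0.8, 0.6)]
        ),
    }
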
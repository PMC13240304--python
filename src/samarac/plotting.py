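"""Optional static figures: efficacy-vs-d curves and burden curves.

Thin matplotlib layer; all numbers come from the library functions.
"""

from __future__ import annotations

import numpy as np

from .clonal import ClonePopulation, CyclePlan, clone_efficacies, simulate_regimen


def plot_efficacy_vs_d(pop: ClonePopulation, alpha: float = 1.0, ax=None,
                       n_points: int = 101):
    """Per-clone and total cycle efficacy as a function of inhibitor
    efficacy d, at the population's current fractions."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ds = np.linspace(0.0, 1.0, n_points)
    per_clone = np.array(
        [clone_efficacies(pop, CyclePlan(drug_on=True, d=d, alpha=alpha)) for d in ds]
    )
    for i, cid in enumerate(pop.ids):
        ax.plot(ds, per_clone[:, i], label=f"clone {cid}")
    ax.plot(ds, per_clone @ pop.fractions, "k--", label="total")
    ax.set_xlabel("SAMHD1-inhibitor efficacy d")
    ax.set_ylabel("cycle efficacy e")
    ax.set_ylim(0, 1)
    ax.legend()
    return ax


def plot_burden_vs_d(pop: ClonePopulation, n_free_cycles: int = 4,
                     alpha: float = 1.0, ax=None, n_points: int = 101):
    """Remaining burden after (n_free_cycles + 1) cycles, the last with the
    inhibitor at efficacy d, versus a single inhibitor-assisted cycle."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ds = np.linspace(0.0, 1.0, n_points)

    def burden(plans):
        return simulate_regimen(pop, plans).burden

    one = [burden([CyclePlan(drug_on=True, d=d, alpha=alpha)]) for d in ds]
    multi = [
        burden(
            [CyclePlan(drug_on=False)] * n_free_cycles
            + [CyclePlan(drug_on=True, d=d, alpha=alpha)]
        )
        for d in ds
    ]
    ax.plot(ds, one, label="1 cycle (with inhibitor)")
    ax.plot(ds, multi, label=f"{n_free_cycles + 1} cycles (inhibitor on last)")
    ax.set_xlabel("SAMHD1-inhibitor efficacy d")
    ax.set_ylabel("remaining burden (relative to untreated)")
    ax.set_yscale("log")
    ax.legend()
    return ax
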
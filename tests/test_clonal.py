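"""Oligoclonal aggregation, selection dynamics, regimen simulation, d-fitting."""

import numpy as np
import pytest

from samarac.clonal import (
    Clone,
    ClonePopulation,
    CyclePlan,
    EradicationError,
    MissingWeightsError,
    NonIdentifiableWarning,
    clone_efficacies,
    fit_drug_efficacy,
    min_cycles_until_drug_beneficial,
    optimize_next_cycle,
    simulate_regimen,
    total_efficacy,
    update_fractions,
    weighted_efficacy,
)
from samarac.model import CloneParams, combined_efficacy, DrugSpec
from samarac.synth import gen_clone_trajectory


def pop_of(triples, fractions=None, **clone_kwargs):
    n = len(triples)
    fractions = fractions or [1.0 / n] * n
    return ClonePopulation(
        tuple(
            Clone(id=f"C{i+1}", fraction=f, params=CloneParams(*t), **clone_kwargs)
            for i, (t, f) in enumerate(zip(triples, fractions))
        )
    )


def random_population(rng, n_clones=None):
    n = n_clones or rng.integers(2, 5)
    f = rng.dirichlet(np.ones(n))
    triples = 0.1 + 0.8 * rng.random((n, 3))
    return pop_of([tuple(t) for t in triples], fractions=list(f))


class TestPopulationValidation:
    def test_fraction_sum_enforced(self):
        with pytest.raises(ValueError, match="sum"):
            pop_of([(0.5, 0.5, 0.5), (0.5, 0.5, 0.5)], fractions=[0.5, 0.6])

    def test_duplicate_ids_rejected(self):
        clones = (
            Clone(id="A", fraction=0.5, params=CloneParams(0.5, 0.5, 0.5)),
            Clone(id="A", fraction=0.5, params=CloneParams(0.4, 0.4, 0.4)),
        )
        with pytest.raises(ValueError, match="duplicate"):
            ClonePopulation(clones)

    def test_partial_weights_rejected(self):
        clones = (
            Clone(id="A", fraction=0.5, params=CloneParams(0.5, 0.5, 0.5),
                  priority_weight=0.5),
            Clone(id="B", fraction=0.5, params=CloneParams(0.4, 0.4, 0.4)),
        )
        with pytest.raises(MissingWeightsError):
            ClonePopulation(clones)


class TestTotalEfficacy:
    def test_two_clone_mixture(self, examples):
        # equal mix of (0.8,0.3,0.7) and (0.8,0.1,0.2); e_i by direct arithmetic
        pop = examples["two_clone_always_beneficial"]
        e1 = 1 - (1 - 0.3 * 0.8) * 0.7   # 0.468
        e2 = 1 - (1 - 0.8 * 0.8) * 0.9   # 0.676
        assert total_efficacy(pop, CyclePlan()) == pytest.approx((e1 + e2) / 2, abs=1e-12)

    def test_three_equal_clones(self, examples):
        pop = examples["three_clone_sequential"]
        expected = (0.816 + 0.82 + 0.856) / 3
        assert total_efficacy(pop, CyclePlan()) == pytest.approx(expected, abs=1e-12)

    def test_single_clone_equals_combined_efficacy(self):
        pop = pop_of([(0.7, 0.4, 0.5)])
        plan = CyclePlan(drug_on=True, d=0.6, alpha=0.8)
        expected = combined_efficacy(CloneParams(0.7, 0.4, 0.5), DrugSpec(0.6, 0.8))
        assert total_efficacy(pop, plan) == pytest.approx(expected, abs=1e-12)

    def test_bounded_by_clone_efficacies(self, rng):
        for _ in range(50):
            pop = random_population(rng)
            plan = CyclePlan(drug_on=True, d=rng.random())
            es = clone_efficacies(pop, plan)
            et = total_efficacy(pop, plan)
            assert es.min() - 1e-12 <= et <= es.max() + 1e-12

    def test_per_clone_drug_override_takes_precedence(self):
        pop = ClonePopulation(
            (
                Clone(id="A", fraction=0.5, params=CloneParams(0.8, 0.3, 0.7),
                      drug_efficacy_override=0.9),
                Clone(id="B", fraction=0.5, params=CloneParams(0.8, 0.1, 0.2)),
            )
        )
        plan = CyclePlan(drug_on=True, d=0.2)
        es = clone_efficacies(pop, plan)
        assert es[0] == pytest.approx(
            combined_efficacy(CloneParams(0.8, 0.3, 0.7), DrugSpec(0.9)), abs=1e-12
        )
        assert es[1] == pytest.approx(
            combined_efficacy(CloneParams(0.8, 0.1, 0.2), DrugSpec(0.2)), abs=1e-12
        )

    def test_dose_label_switches_parameters(self):
        pop = ClonePopulation(
            (
                Clone(id="A", fraction=1.0, params=CloneParams(0.8, 0.1, 0.7),
                      dose_params={"low": (0.4, 0.9)}),
            )
        )
        low = total_efficacy(pop, CyclePlan(dose_label="low"))
        assert low == pytest.approx(
            combined_efficacy(CloneParams(0.4, 0.1, 0.9), DrugSpec(0.0)), abs=1e-12
        )
        with pytest.raises(KeyError):
            total_efficacy(pop, CyclePlan(dose_label="missing"))


class TestWeightedEfficacy:
    def test_weights_equal_fractions_match_total(self, rng):
        f = rng.dirichlet(np.ones(3))
        triples = [tuple(t) for t in 0.1 + 0.8 * rng.random((3, 3))]
        pop = ClonePopulation(
            tuple(
                Clone(id=f"C{i}", fraction=fi, params=CloneParams(*t),
                      priority_weight=fi)
                for i, (t, fi) in enumerate(zip(triples, f))
            )
        )
        plan = CyclePlan()
        assert weighted_efficacy(pop, plan) == pytest.approx(
            total_efficacy(pop, plan), abs=1e-12
        )

    def test_degenerate_weight_selects_one_clone(self, examples):
        base = examples["three_clone_sequential"]
        pop = ClonePopulation(
            tuple(
                Clone(id=c.id, fraction=c.fraction, params=c.params,
                      priority_weight=w)
                for c, w in zip(base.clones, (1.0, 0.0, 0.0))
            )
        )
        assert weighted_efficacy(pop, CyclePlan()) == pytest.approx(0.816, abs=1e-12)

    def test_clinician_weighting(self, examples):
        base = examples["three_clone_sequential"]
        pop = ClonePopulation(
            tuple(
                Clone(id=c.id, fraction=c.fraction, params=c.params,
                      priority_weight=w)
                for c, w in zip(base.clones, (0.5, 0.25, 0.25))
            )
        )
        assert weighted_efficacy(pop, CyclePlan()) == pytest.approx(0.827, abs=1e-12)

    def test_missing_weights_error(self, examples):
        with pytest.raises(MissingWeightsError):
            weighted_efficacy(examples["three_clone_sequential"], CyclePlan())


class TestUpdateFractions:
    def test_first_cycle_of_sequential_example(self, examples):
        pop = examples["three_clone_sequential"]
        new = update_fractions(pop, [0.816, 0.82, 0.856])
        np.testing.assert_allclose(
            new.fractions, [0.36220472, 0.35433071, 0.28346457], atol=1e-7
        )

    def test_equal_efficacies_leave_fractions_unchanged(self, rng):
        pop = random_population(rng)
        new = update_fractions(pop, [0.4] * len(pop))
        np.testing.assert_allclose(new.fractions, pop.fractions, atol=1e-12)

    def test_eradicated_clone_vanishes(self):
        pop = pop_of([(0.5, 0.5, 0.5), (0.4, 0.4, 0.4)], fractions=[0.5, 0.5])
        new = update_fractions(pop, [1.0, 0.0])
        np.testing.assert_allclose(new.fractions, [0.0, 1.0], atol=1e-12)

    def test_total_eradication_raises(self):
        pop = pop_of([(0.5, 0.5, 0.5), (0.4, 0.4, 0.4)], fractions=[0.5, 0.5])
        with pytest.raises(EradicationError):
            update_fractions(pop, [1.0, 1.0])

    def test_conservation_and_selection_direction(self, rng):
        """Fractions stay normalised; clones below-average efficacy expand."""
        for _ in range(100):
            pop = random_population(rng)
            e = rng.random(len(pop)) * 0.95
            e_total = float(pop.fractions @ e)
            new = update_fractions(pop, e)
            assert new.fractions.sum() == pytest.approx(1.0, abs=1e-9)
            grew = new.fractions > pop.fractions + 1e-12
            shrank = new.fractions < pop.fractions - 1e-12
            assert np.all(grew == (e < e_total - 1e-12))
            assert np.all(shrank == (e > e_total + 1e-12))

    def test_monoclonal_fixed_point(self):
        pop = pop_of([(0.7, 0.4, 0.5)])
        new = update_fractions(pop, [0.61])
        assert new.fractions[0] == pytest.approx(1.0, abs=1e-12)


class TestSimulateRegimen:
    def test_single_cycle_burden(self, examples):
        trace = simulate_regimen(examples["three_clone_sequential"], [CyclePlan()])
        assert trace.burden == pytest.approx(1 - (0.816 + 0.82 + 0.856) / 3, abs=1e-12)

    def test_inert_treatment_changes_nothing(self):
        pop = pop_of([(0.0, 0.0, 0.0), (0.0, 0.0, 0.0)], fractions=[0.3, 0.7])
        trace = simulate_regimen(pop, [CyclePlan(drug_on=True, d=0.8)] * 3)
        assert trace.burden == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(trace.final_fractions, [0.3, 0.7], atol=1e-12)

    def test_burden_is_product_of_cycle_survivals(self, rng):
        for _ in range(20):
            pop = random_population(rng)
            plans = [CyclePlan(drug_on=bool(rng.integers(2)), d=rng.random())
                     for _ in range(4)]
            trace = simulate_regimen(pop, plans)
            expected = np.prod([1 - r.e_total for r in trace.records])
            assert trace.burden == pytest.approx(expected, rel=1e-12)

    def test_eradication_truncates_with_zero_burden(self):
        pop = pop_of([(1.0, 0.0, 0.0), (1.0, 0.0, 0.0)], fractions=[0.5, 0.5])
        trace = simulate_regimen(pop, [CyclePlan()] * 3)
        assert trace.eradicated and trace.burden == 0.0
        assert len(trace.records) == 1

    def test_trace_frame_is_tidy(self, examples):
        trace = simulate_regimen(examples["three_clone_sequential"], [CyclePlan()] * 2)
        df = trace.to_frame()
        assert list(df.columns) == [
            "cycle", "clone_id", "fraction_before", "efficacy",
            "fraction_after", "e_total", "burden",
        ]
        assert len(df) == 6
        sums = df.groupby("cycle")["fraction_after"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_strong_inhibitor_on_last_cycle_beats_ara_c_alone(self, examples):
        """Five cycles with the inhibitor (d=1) on the fifth outperform five
        ara-C-only cycles, but a half-strength inhibitor does not."""
        pop = examples["three_clone_sequential"]
        free = simulate_regimen(pop, [CyclePlan()] * 5).burden
        strong = simulate_regimen(
            pop, [CyclePlan()] * 4 + [CyclePlan(drug_on=True, d=1.0)]
        ).burden
        weak = simulate_regimen(
            pop, [CyclePlan()] * 4 + [CyclePlan(drug_on=True, d=0.5)]
        ).burden
        assert strong < free < weak


class TestMinCycles:
    def test_sequential_example_needs_four_cycles(self, examples):
        pop = examples["three_clone_sequential"]
        assert min_cycles_until_drug_beneficial(pop, d=1.0) == 4

    def test_always_beneficial_population_needs_none(self, examples):
        pop = examples["two_clone_always_beneficial"]
        assert min_cycles_until_drug_beneficial(pop, d=0.3) == 0

    def test_zero_efficacy_drug_never_helps(self, examples):
        pop = examples["three_clone_sequential"]
        assert min_cycles_until_drug_beneficial(pop, d=0.0, max_cycles=10) is None

    def test_crossing_only_for_strong_inhibition(self, examples):
        """The inhibitor becomes worth adding within a short regimen only
        when its efficacy approaches 1."""
        pop = examples["three_clone_sequential"]
        assert min_cycles_until_drug_beneficial(pop, d=0.5, max_cycles=6) is None


class TestOptimizeNextCycle:
    def test_prefers_ara_c_alone_initially(self, examples):
        pop = examples["three_clone_sequential"]
        cands = [CyclePlan(), CyclePlan(drug_on=True, d=1.0)]
        best = optimize_next_cycle(pop, cands)
        assert best.index == 0
        assert best.score == pytest.approx((0.816 + 0.82 + 0.856) / 3, abs=1e-12)

    def test_prefers_inhibitor_after_four_free_cycles(self, examples):
        pop = examples["three_clone_sequential"]
        for _ in range(4):
            pop = update_fractions(pop, clone_efficacies(pop, CyclePlan()))
        best = optimize_next_cycle(pop, [CyclePlan(), CyclePlan(drug_on=True, d=1.0)])
        assert best.index == 1

    def test_single_candidate_returned(self, examples):
        plan = CyclePlan(drug_on=True, d=0.4)
        best = optimize_next_cycle(examples["mono_conditional"], [plan])
        assert best.plan is plan

    def test_ties_break_to_earliest(self, examples):
        plan = CyclePlan()
        best = optimize_next_cycle(examples["mono_conditional"], [plan, CyclePlan()])
        assert best.index == 0


class TestFitDrugEfficacy:
    def test_noise_free_inversion(self, examples):
        pop = examples["three_clone_sequential"]
        es = clone_efficacies(pop, CyclePlan(drug_on=True, d=0.5))
        post = update_fractions(pop, es).fractions
        fit = fit_drug_efficacy(pop, post)
        assert fit.identifiable
        assert fit.d == pytest.approx(0.5, abs=1e-6)

    def test_recovery_from_binomial_sampling(self, examples):
        pop = examples["three_clone_sequential"]
        traj = gen_clone_trajectory(
            pop, [CyclePlan(drug_on=True, d=0.7)], n_cells=10**6, seed=42
        )
        post = traj[traj["cycle"] == 1].set_index("clone_id")["fraction"]
        fit = fit_drug_efficacy(pop, post.reindex(list(pop.ids)).to_numpy())
        assert abs(fit.d - 0.7) < 0.02

    def test_identical_clones_not_identifiable(self):
        pop = pop_of([(0.7, 0.4, 0.5), (0.7, 0.4, 0.5)], fractions=[0.5, 0.5])
        with pytest.warns(NonIdentifiableWarning):
            fit = fit_drug_efficacy(pop, [0.5, 0.5])
        assert not fit.identifiable

    def test_recovery_over_random_populations(self, rng):
        """Parameter recovery within 0.02 at 10^6 cells, random populations."""
        errors = []
        for i in range(20):
            pop = random_population(rng, n_clones=3)
            d_true = float(rng.uniform(0.1, 0.9))
            traj = gen_clone_trajectory(
                pop, [CyclePlan(drug_on=True, d=d_true)], n_cells=10**6,
                seed=1000 + i,
            )
            post = (
                traj[traj["cycle"] == 1]
                .set_index("clone_id")["fraction"]
                .reindex(list(pop.ids))
                .to_numpy()
            )
            fit = fit_drug_efficacy(pop, post)
            errors.append(abs(fit.d - d_true))
        assert max(errors) < 0.02
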
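# Methods

## Model

One treatment cycle of one AML clone is modelled as two independent
Bernoulli "kill routes": the ara-C route with probability
`x_imp = (1 − z_red)·x` and the direct SAMHD1 tumour-suppressor route with
probability `y_red`. Without an inhibitor, `z_red = z` and `y_red = y`;
with a SAMHD1 inhibitor of ara-CTPase efficacy `d` and specificity
`α = d_y/d_z ∈ [0, 1]`, `y_red = (1 − αd)·y` and `z_red = (1 − d)·z`. A
cell survives only if it escapes both routes, so the cycle efficacy is

    e(d, α) = 1 − (1 − x_imp)(1 − y_red).

The statistical-independence assumption means SAMHD1 expression does not
modulate the downstream lethality of un-hydrolysed ara-CTP, and ara-C does
not modulate SAMHD1's anti-proliferative activity. All parameters are
phenomenological probabilities per cycle; no enzyme kinetics, dNTP-pool
dynamics or pharmacokinetics are modelled, and ara-C dose enters only
through the (x, z) values supplied per dose label.

The benefit of adding the inhibitor factorises as

    e(d) − e(0) = d · [xz + αxy − αy − (1+α)xyz + αxyz·d],

a linear, non-decreasing function of `d` inside the bracket. For interior
parameters its sign flips at

    d* = (1+α)/α − 1/z − 1/(αy) + 1/(xz),

which drives both the scalar classifier and the vectorised phase grids.
Two consequences worth knowing: the inhibitor is never beneficial when
`y > x` (the suppressor outguns fully active ara-C), and never beneficial —
independent of x and z — when `y > 1/(1 + α − αd)`. Lowering α (a more
ara-CTPase-specific inhibitor) lowers d* monotonically whenever `y < 1`,
so the beneficial region of parameter space only grows with specificity.

An oligoclonal AML is N clones with fractions summing to 1. Cycle efficacy
is the mixture `e_total = Σ f_i e_i` (law of total probability over clone
membership); an optional clinician-weighted objective `Σ w_i e_i` is
provided as an alternative score only — it never feeds the fraction
update. After a cycle the fractions renormalise to
`f_i' = f_i (1−e_i)/(1−e_total)`, and the remaining burden after k cycles
is `Π (1 − e_total)`, expressed relative to the untreated expectation (net
growth between cycles is absorbed by that normalisation). The simulator is
deterministic expected-value dynamics; finite-population stochasticity is
available separately in the synthetic-data generators. The clone roster is
fixed for the length of a regimen: clones emerging mid-treatment must be
measured and supplied as a new population.

## Parameters

| symbol | meaning | range | default |
| --- | --- | --- | --- |
| x | ara-C efficacy absent SAMHD1 interference | [0, 1] | per clone, required |
| y | direct SAMHD1 suppressor efficacy | [0, 1] | per clone, required |
| z | SAMHD1-mediated fractional reduction of x | [0, 1] | per clone, required |
| d | inhibitor efficacy against the ara-CTPase function | [0, 1] | 0 |
| α | specificity ratio d_y/d_z (1 = symmetric) | [0, 1] | 1 |
| f_i | clone fraction | Σ = 1 | equal shares in examples |
| CV | relative viability-measurement error | ≥ 0 | 0.094 |

All quantities are per treatment cycle and unitless; ara-C concentration
(µM) appears only as the index of dose-response tables.

## Estimation

`estimate_x` uses the SAMHD1-null condition (undiluted Vpx), where
`e = x`, so `x(c) = 1 − mean viability`. `estimate_y` works at zero ara-C,
where `e = y`, on the **ratio** of a condition's mean viability to the
best-surviving condition group's mean — this makes the estimate invariant
to the assay's absolute scale; endogenous-SAMHD1 y comes from the pooled
empty-VLP/no-VLP controls, and SAMHD1-reduced conditions use y = 0 (a step,
not an interpolation: reducing SAMHD1 modestly already restores full
viability, and no viability gradient with SAMHD1 level below that is
modelled). `estimate_z` inverts the efficacy formula exactly; inversions
landing slightly outside [0, 1] are reported raw, flagged, and clamped with
a warning — never silently.

Uncertainty: per-concentration CV = sample SD / mean (ddof = 1, the
standard choice at n = 6), averaged into a single relative error scale
σ_v = CV·v. First-order delta-method propagation with independent errors
carries σ_v, σ_x, σ_y through the z inversion using its analytic partial
derivatives (∂z/∂v = 1/(x(1−y)), etc.); the propagated σ_z diverges as
x → 0, correctly reflecting that z is unidentifiable without an ara-C
signal. σ for y defaults to the standard error of the condition mean; the
single-measurement SD is available via `sd_method="sd"`.

`fit_drug_efficacy` recovers d from pre/post clonal fractions by least
squares on the ratios f_i'/f_i against (1−e_i(d))/(1−e_total(d)). The loss
is scanned on a dense grid (step 1e-3) and polished by bounded 1-D
minimisation; a flat residual profile (e.g. identical clones) triggers a
non-identifiability warning instead of a spurious estimate.

## Numerical choices

- Probability validation accepts a slack of 1e-9 (clamped), absorbing float
  round-off from upstream arithmetic; anything further out is rejected.
- "Beneficial" means *strictly* greater efficacy; differences within 1e-12
  are ties, so degenerate parameter combinations where the inhibitor has
  identically zero effect classify as NEUTRAL rather than as noise-driven
  benefit. Threshold formulas divide by x, y, z, α; when any of these is
  zero `benefit_threshold` raises a degenerate-parameter error and
  `classify_regime` resolves the regime from the sign of the closed-form
  gain instead, with ±∞ threshold sentinels.
- The drug is parameterised by (d, α), not (d_y, d_z); converters are
  provided.
- Fraction updates divide by the realised survivor sum rather than
  1 − e_total (identical in exact arithmetic, stable over many cycles);
  eradication (e_total = 1 within 1e-12) ends a simulation with burden 0
  rather than dividing by zero.
- `min_cycles_until_drug_beneficial` uses the myopic criterion: the next
  single cycle's e_total with versus without the drug, matching how
  per-cycle efficacies are compared clinically; full-horizon optimisation
  is available by iterating `optimize_next_cycle` (ties break to the
  earliest candidate).
- Boundary surfaces z*(x, y) are found by bracketed Brent root-finding to
  1e-10; the threshold is strictly decreasing in z for x < 1, so a sign
  change over (0, 1] brackets a unique root, and absence of a root is
  recorded as NaN (the whole z-range lies on one side), not an error.
- Phase grids default to 41 points per axis (~7·10^4 closed-form
  evaluations, well under a second); grid faces at 0 and 1 go through the
  degenerate branches.
- Every stochastic operation takes an explicit seed (default documented in
  `samarac.model.DEFAULT_SEED`); identical seeds give byte-identical
  outputs.

## Synthetic data

`gen_viability_table` emulates the structure of Vpx/VLP dose-response
assays: model viabilities `1 − e` per condition and concentration,
perturbed by multiplicative Gaussian noise of a stated CV (default 0.094,
the calibrated assay noise) truncated to [0, 1]. `gen_clone_trajectory`
draws per-clone survivor counts binomially per cycle and recomputes
observed fractions; at large cell counts it converges to the deterministic
update (verified at 10^7 cells, tolerance 1e-3). The generators reproduce
structure and noise scale, not any measured dataset: real assays can have
concentration-dependent CVs, correlated replicate errors, plate effects,
and non-Gaussian tails, none of which are emulated — so passing recovery
tests demonstrate estimator correctness under the stated noise model, not
robustness to real-assay pathologies. Worked-example clone configurations
ship in `example_populations()`.

## Test and benchmark problem sizes

Property tests use 10^4-point random parameter grids for the closed-form
identities, 10^6 cells for Monte-Carlo agreement (4-SE bands) and
drug-efficacy recovery (tolerance 0.02), 6 replicates at 9.4% CV for
viability-table recovery (3 propagated SDs), and 15-21 points per axis for
phase-grid monotonicity checks — sizes at which every statistical check is
comfortably resolved and the whole suite runs in seconds.

## Known limitations

- Statistical independence of the two kill routes is assumed throughout;
  backgrounds that couple ara-C sensitivity and SAMHD1 response need
  conditional-probability extensions that are out of scope here.
- Viability assays are treated as proxies for clone-intrinsic response
  parameters, not as direct measurements of leukaemic-stem-cell
  eradication.
- The fraction update is deterministic; extinction of small clones by
  sampling noise only appears in the synthetic trajectory generator.
- y is modelled as a step function of SAMHD1 level (endogenous vs reduced),
  as the calibration data show no intermediate gradient; other cell lines
  may differ.
- No toxicity, microenvironment, or combination-partner effects: the model
  covers the ara-C/SAMHD1 axis only, and parameters must be re-estimated
  when the clinical context changes.
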
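# Methods

`persevo` simulates the evolution of bacterial populations that are
intermittently exposed to a bactericidal antibiotic, tracking the joint
selection of *resistance* (growth at elevated drug concentrations, quantified
by the MIC) and *persistence* (a phenotypically dormant subpopulation that is
not killed by the drug).  This note documents the model, its parameters, the
numerical choices, what the synthetic-data generators do and do not emulate,
and the known limitations.

## Model

### Genotype space

Cells belong to one of 30 mutant classes, each a pair of a resistance level
`l_R ∈ {0..5}` (log2 fold change of the MIC over the ancestral 2 µg/ml) and a
persistence level `l_P ∈ {0..4}` (log10 fold change of the maximum
regular→persister switching rate over the ancestral 10⁻⁴·⁵ h⁻¹).  Class
`(l_R, l_P)` therefore has MIC `2·2^{l_R}` µg/ml and maximum switching rate
`10^{-4.5+l_P}` h⁻¹.  The ancestor is `(0, 0)`; the classes are indexed
`l_R`-major so serialized outputs are stable.

### Growth and killing

The net growth rate (change in log10 cell count per hour) of class *i* at
antibiotic concentration `AB` follows a four-parameter Hill dose–response

    ψ_i(AB) = ψ_max − (ψ_max − ψ_min) · r / (r − ψ_min/ψ_max),
    r = (AB/MIC_i)^κ_AB,

which is positive below the MIC, crosses zero exactly at the MIC, and
saturates at `ψ_min`.  Within one interval `Δt`, regular cells divide with
probability

    g_i = log2(10^{ψ_i Δt}) · n        (ψ_i > 0)

where the nutrient level `n ∈ [0, 1]` (fraction of fresh medium; `n =
(K−N)/K` at demographic equilibrium) acts as a logistic factor, or die with
probability

    g_i = 1 − 10^{ψ_i η(n) Δt}          (ψ_i < 0),
    η(n) = 1 / (1 + (n_half/n)^κ_n),

the Hill modifier `η` capturing that the drug kills metabolically active
cells only (`η(0) = 0` by the limit convention: no killing in spent medium).
At `ψ_i = 0` (dose exactly at the MIC) the growth branch applies with `g = 0`.

### Persister switching

Regular cells switch to the persister state at rate `a_i(n) = a_{i,max}(1−n)`
(maximal in stationary phase) and persisters revert at `b(n) = b_max·n`
(maximal in fresh medium).  Persisters do not grow, are not killed by the
antibiotic, and do not mutate.

### Mutation

Only daughters produced by a division may mutate, and only to classes with
equal-or-higher levels (beneficial mutations; reversions and fitness costs
are outside the model's scope).  The relative weight of a jump decays
tenfold per lattice unit, `w ∝ 10^{-(Δl_R + Δl_P)}` — an exponential
distribution of fitness effects over the discrete grid; a simultaneous
`(Δl_R ≥ 1, Δl_P ≥ 1)` jump is a single kernel entry (one pleiotropic
mutation).  Weights are scaled so every class with at least one permitted
target mutates with total probability `m` per division (row normalization).
The paper-facing alternative — one global scale constant — is available as
`normalization="global"`, anchored so the ancestor row sums to `m`; the two
coincide on the ancestor row and differ only for classes whose target set is
truncated by the lattice edge.  The ablation kernel
(`allow_persistence=False`) zeroes all `Δl_P > 0` targets before
renormalizing, holding persistence at the ancestral level.

### Stochastic update

Dynamics are advanced with a binomial τ-leap (fixed `Δt = 0.5` h): division
and death counts are binomial draws at the per-cell probabilities above,
daughter mutations a binomial-then-multinomial draw over the kernel row, and
switching counts binomial draws at `1 − exp(−rate·Δt)`.  Within a step the
order is growth (with daughter mutation) → death → switching → nutrient
depletion; daughters may not divide again within the step.  Nutrients
deplete by the *net* population increase over the carrying capacity,
`Δn = −max(ΔN_tot, 0)/K`, clamped to `[0, 1]` — the floor reflects that the
depletion rule describes growth; cell death does not return nutrients to the
medium.  Extinction (zero live cells) is absorbing.

### Treatment protocol

Each 24-h cycle: (1) dilution of the stationary culture into fresh medium at
culture-to-total ratio `1 − n0`, setting the nutrient level to `n0`; (2) 5 h
of treatment at the chosen dose; (3) wash (instantaneous drug removal) and
1:100 transfer into fresh medium (`n = 1`); (4) 19 h of drug-free regrowth.
Both transfers draw a multinomial sample over all regular and persister
compartments plus a dead-cell pool at their current frequencies, mirroring
pipetting from a well containing live and dead cells; the dead pool
accumulates between transfers and is carried through them as inert
bookkeeping.  A simulation starts from 10³ regular ancestral cells plus one
persister in fresh medium and runs one drug-free growth phase before the
first treatment (the in-vitro cultures grew overnight before treatment 1;
`initial_growth=False` starts at the first treatment instead).  Runs last 10
cycles; the per-cycle survival fraction is live cells after treatment over
live cells at treatment initiation, clipped at 1 as a CFU ratio would be.

## Default parameters

| parameter | default | units | meaning |
|---|---|---|---|
| ψ_max | 0.6 | log10 cells/h | drug-free growth: one division per cell per 30 min at n = 1 |
| ψ_min | −10 | log10 cells/h | saturating kill rate; ψ(400 µg/ml)·η(1) ≈ −6.12 log10/h for the ancestor |
| κ_AB, κ_n | 1 | – | Hill coefficients |
| n_half | 0.5 | – | nutrient half-saturation of killing |
| b_max | 0.1 | 1/h | persister reawakening in fresh medium |
| Δt | 0.5 | h | τ-leap interval |
| K | 10⁶ | cells | carrying capacity |
| m | 10⁻⁴ | per division | overall beneficial-mutation probability |
| inoculum | 10³ + 1 | cells | regular + persister, ancestor only |
| cycle | 5 h + 19 h ×10 | – | treatment + regrowth, 1:100 post-dilution |

The grid experiment defaults to doses {12.5, 25, 50, 100, 200, 400} µg/ml ×
nutrient levels {0.1..0.9} with 1000 replicate populations per condition.
The dose axis follows the named experimental concentrations; the nutrient
axis is a uniform reconstruction spanning the named levels — the exact grid
behind the published condition totals is not printed, so totals summed over
grid subsets inherit this reconstruction uncertainty (both axes are
configurable).

## Classification and summaries

A surviving population counts as having evolved resistance (persistence)
when at least 30% of its live cells — regular plus persister — are in
classes with `l_R > 0` (`l_P > 0`); the threshold comparison is a strict ≥.
Condition summaries report extinction counts, the four
resistance-only/persistence-only/both/neither categories, and
abundance-weighted mean levels over survivors (a dominant-class summary can
be recovered from the per-population occupancy vectors that every grid run
emits).

## Time–kill fitting

Survival under treatment of a population with initial persister fraction
`P0` follows the biphasic decay `S(τ) = (1−P0)e^{−k_n τ} + P0 e^{−k_p τ}`.
`fit_biphasic` minimizes least squares on the log10 scale with a
`(log10 P0, log k_n, log k_p)` parameterization (positivity by construction),
a 12-point multi-start grid (log10 P0 ∈ {−1.5, −3, −4.5} × k_n ∈ {2, 10} ×
k_p ∈ {0.05, 0.5}), and optional per-replicate additive offsets with a
sum-to-zero constraint — a fixed-effect approximation of a random replicate
effect that absorbs relative replicate shifts but, by construction, not a
shift common to all replicates (the curve is anchored at `S(0) = 1`).
Offsets and noise apply to post-baseline rows only; fractions of exactly 0
(below plating detection) are excluded from the log-scale fit and counted.
Since the two phases are exchangeable in the model, fits are reported with
`k_n ≥ k_p`; when the fitted fast phase carries no weight (`P0 → 1`), `k_n`
is flagged unidentifiable.  `derive_engine_parameters` maps `k_n/ln 10` onto
the engine's log10 kill-rate scale (`−ψ·η`) and `k_p` onto the
persister-exit-limited scale (`b`).

Calibration of the fitter on synthetic data is an information-limited
exercise: with the protocol's sampling times (0, 1, 2, 3, 5, 8 h), three
replicates and noise sd 0.15 on log10 survival, the slow-phase rate is well
identified near `k_p ≈ 0.5` h⁻¹ (recovery within ±20% in ~96% of datasets)
but not near `k_p ≈ 0.2` h⁻¹, where the Cramér–Rao bound for sd(`k_p`)
already exceeds 20% of the true value — no estimator can be calibrated to
that tolerance from that design, which is why the recovery test uses the
identifiable point.

## Synthetic data and what passing tests show

The package generates all of its own test inputs: simulated populations from
the engine itself and kill-curve tables from the biphasic forward model with
log-normal measurement noise and optional replicate offsets.  The generators
emulate the *structure* of the experimental data (sampling times, replicate
layout, detection limits) but none of its biology beyond the model: no
fitness costs, no deleterious or reverting mutations, no spatial structure
or cell–cell interactions, no drug carry-over, a discrete effect-size grid,
and measurement noise that is exactly log-normal.  Passing tests therefore
validate the implementation against its own mathematical specification and
its qualitative agreement with the published selection patterns — not the
biological accuracy of the model for any particular organism or drug.

## Numerical and design choices

- **Event order within a step** (growth → death → switching → depletion) is
  not dictated by the model statement; this order applies mutation exactly
  to the cells that divided and is fixed and documented.  At the default
  rates the alternative orders differ at O(rate²·Δt²).
- **Switching probabilities** use `1 − exp(−rate·Δt)` rather than `rate·Δt`
  so they remain probabilities for any parameterization (difference < 0.3%
  at the default rates).
- **Exactness regime.** For death and switching the τ-leap per-cell law over
  one step is the exact exponential law, so on small systems the engine's
  outcome distribution matches an exact event-driven (Gillespie) simulation
  — the test suite verifies this on ≤20-cell, 2-class instances.  The
  discrete step does bar multiple transitions per cell per interval, so when
  two fast processes compete within a step (e.g. strong killing against fast
  switching, cross-terms O(k·a·Δt²)) the τ-leap deviates from the
  continuous-time chain; division likewise has no exact continuous-time
  counterpart because daughters may not re-divide within a step.  Growth is
  therefore validated against the deterministic logistic recursion it
  implies, rather than against an SSA.
- **Seed discipline.** Replicate `r` of condition `c` uses
  `SeedSequence(base_seed, spawn_key=(c, r))`; identical configuration and
  base seed give bit-identical outputs under any execution order.
- **Dilution size** is `round(keep_fraction · (live + dead))`; a
  `keep_fraction` of exactly 1 is the identity (no resampling noise).
- **Degenerate inputs.** Extinct states pass through `step` unchanged;
  extinct populations raise on classification/summary (undefined rather
  than zero); `η(0) = 0`, division probability capped at 1.

## Limitations

- No pharmacokinetics: the drug concentration is a step function (exact dose
  during treatment, zero otherwise).
- No fitness costs, deleterious mutations, or continuous effect sizes; the
  30-class grid caps evolvable resistance at MIC 64 µg/ml.
- The mixed-model replicate effect is approximated by fixed sum-to-zero
  offsets; a common replicate shift is absorbed into `P0`.
- The extinction regression is fitted linearly on proportions (matching the
  published analysis), not as a logistic model.
- Populations are small (K = 10⁶) relative to laboratory cultures, chosen
  for mutational supply comparable to the bench experiment; larger
  populations would see more rare large-effect mutations.
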
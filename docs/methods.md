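# Methods

## Model representation and conventions

A model is a list of metabolites (rows of the stoichiometric matrix S) and
reactions (columns) with flux bounds in mmol gDCW⁻¹ h⁻¹, an optional
boolean gene–protein–reaction (GPR) rule per reaction, and a biomass
objective reaction.  Bound conventions follow common genome-scale
practice: irreversible reactions 0…1000, reversible −1000…1000; exchange
reactions touch exactly one metabolite, with negative flux meaning uptake
and positive flux secretion.

A *condition* is a named medium: explicit exchange bounds plus carbon
metadata.  Applying a condition replaces the listed bounds and closes the
uptake side of every other known carbon-source exchange, enforcing growth
on a single carbon source.  Oxygen and mineral-medium exchanges stay open
at ±1000 unless the condition overrides them; the wildtype oxygen uptake
bound is taken as −1000 (the generic "unconstrained" convention) since no
measured value is available.  Substrate uptake rates are
carbon-proportional: with glucose (6 C) at −16 mmol gDCW⁻¹ h⁻¹, a
substrate with *n* carbons gets −16·6/*n* (xylose/arabinose −19.2,
glycerol −32).  The toy fixtures scale this to −10 for the 6-carbon
source to keep optima at round numbers.

## Simulation methods

All four methods are linear programs solved with HiGHS (dual simplex,
feasibility/optimality tolerances 1e-9); fluxes are never rounded before
serialisation (9 significant digits at output).

* **FBA** — max c·v s.t. S·v = 0, lb ≤ v ≤ ub.
* **pFBA** — two stages: FBA gives z\*; then minimise Σⱼ(vⱼ⁺ + vⱼ⁻) with
  v = v⁺ − v⁻ ≥ 0 splits subject to c·v ≥ z\*.  The relaxation fraction is
  0 (strict optimum): no explicit slack is added beyond the solver's own
  1e-9 feasibility tolerance, so pFBA growth equals FBA growth to within
  1e-9 by construction.
* **LMOMA** — given a wildtype reference w, minimise Σⱼ(δⱼ⁺ + δⱼ⁻) with
  vⱼ − wⱼ = δⱼ⁺ − δⱼ⁻ under the perturbed bounds.  Growth is an outcome,
  never a constraint.
* **MiMBL** — minimise Σᵢ(εᵢ⁺ + εᵢ⁻) with tᵢ − τᵢ = εᵢ⁺ − εᵢ⁻, where the
  mutant turnover tᵢ = ½ Σⱼ |Sᵢⱼ|(vⱼ⁺ + vⱼ⁻) is linear in the split
  fluxes.  Caveat: the split is not forced tight, so the optimiser may
  loosen a split (vⱼ⁺, vⱼ⁻ both positive) to raise a turnover toward τᵢ.
  This is accepted — minimisation keeps it in check, and the identity
  property (distance exactly 0 on the unperturbed model) pins the
  behaviour; the turnover distance should be read as a lower bound on
  adjustment, not a unique flux prediction.

The *reference state* is the wildtype pFBA solution under the same
condition (pFBA being the stated wildtype method), with turnovers
computed from the tight split of w.  Reported LMOMA/MiMBL distances below
1e-9 are clamped to exactly 0: at that magnitude they are simplex
round-off, and the clamp makes the identity property exact.

Degenerate alternate optima are reported from the solver's vertex as-is;
benchmark comparisons on deposited models therefore use ±0.01 on
production rates and ±0.001 on growth rates.

## Modification semantics

Factors multiply the *wildtype flux* (not the original bounds), matching
the usual strain-design reading of "a decrease in the flux value through
the reaction compared to wildtype":

* factor 0 → bounds (0, 0) — knockout;
* 0 < f < 1 → sign-preserving cap, bounds (min(0, f·w), max(0, f·w)).  A
  cap (inequality), not an equality pin, so lethal combinations stay
  representable instead of becoming spuriously infeasible;
* f > 1 → sign-preserving floor |v| ≥ f·|w| with the original outer bound
  retained; a floor that exceeds the outer bound marks the model
  infeasible (a scored-as-infeasible candidate, not an exception).  For
  w = 0 a floor is a no-op.

Gene factors propagate through GPRs with AND → min and OR → max over
child factors, the continuous generalisation of boolean knockout logic
(the binary case — 0 knocks out a complex through AND, an isozyme rescues
through OR — is the only behaviour fixed by convention; min/max is chosen
for monotonicity and continuity, and is property-tested as monotone).
Genes absent from a factor map default to 1.

## Strain design

Candidates hold ≤ K modifications with distinct targets (default K = 2).
Each candidate is simulated with the configured method (pFBA, LMOMA or
MiMBL against the wildtype reference) and scored on two maximised
objectives: BPCY = growth × production / |substrate uptake| (0 when
uptake is 0) and the production rate itself.

The optimizer is SPEA2 with an external archive: strength/raw fitness
plus k-th-nearest-neighbour density (k = √N), environmental selection
with iterative nearest-neighbour truncation, binary-tournament mating,
uniform crossover (p = 0.7) over fixed-length modification slots, and
per-slot mutation (p = 0.2: re-draw target, re-draw factor, or clear).
Defaults: population 100, archive 100, 5000 evaluations, factor grid
{0, 1/32, 1/16, 1/8, 1/4, 1/2, 2, 4, 8, 16, 32} — the powers-of-two
scale modification factors are conventionally drawn from.  Evaluations
are memoised by genotype; the budget counts unique simulations, and a
generation cap prevents spinning when a small search space is exhausted.
All randomness flows from one seeded generator, so identical seeds give
identical archives.  Infeasible candidates never enter the archive; if
everything evaluated is infeasible the archive is empty with a warning.
`enumerate_designs` evaluates every candidate exhaustively (guarded at
1e5 evaluations) and is the oracle the optimizer is tested against.

## Synthetic fixtures and what green tests establish

`btd_core_model()` is a hand-built ~20-reaction network: glucose/glycerol
uptake, lumped glycolysis (glc → 2 pyr + 2 ATP + 2 NADH), lumped TCA
(pyr → 3 CO₂ + 4 NADH + ATP), lumped respiration at P/O = 2 (chosen for
integer arithmetic; any positive value preserves the tested properties),
the three-step 2,3-BTD branch with an isozyme pair on its GPRs, and a
biomass reaction (2 pyr + 12 ATP per unit — chosen so optimal growth on
glucose at −10 is exactly 8).  The optional forced ATP drain (lower
bound 6) plants a provably-optimal knockout for optimizer tests; the
oxygen-limited design condition (O₂ at −9) makes product secretion and
the growth/production trade-off active.

`random_consistent_model(spec)` generates seeded networks whose internal
reactions are balanced against strictly positive per-metabolite masses,
so the internal S has a strictly positive left null vector and mass
cannot be created except through exchanges; a backbone chain guarantees a
carbon → biomass route.

These fixtures reproduce the *structure* the analysis assumes —
stoichiometric consistency, redox/ATP coupling, a secreting product
branch — not the scale or redundancy of a genome-scale model (thousands
of reactions, extensive alternate optima, realistic biomass composition).
Green tests therefore establish correctness of the programs and their
invariants, not quantitative agreement with any published genome-scale
number; those benchmarks live behind the `reproduce` command and require
the deposited iMK1321 files.

## Numerical choices

* LP solver HiGHS dual simplex, tolerances 1e-9; the validation oracle
  uses interior-point on independently built dense programs.
* Steady-state and bound residuals of any reported optimal solution are
  audited to ≤ 1e-6.
* Distances < 1e-9 report as exactly 0 (see above).
* Ties in enumeration and archive ordering break on the candidate
  genotype, making all outputs deterministic.

## Known limitations

* No thermodynamic, enzyme-capacity or regulatory constraints; no FVA or
  quadratic MOMA.
* MiMBL's loose-split caveat above.
* SPEA2 solution *counts* are stochastic-search output and are never
  asserted; only archive quality (oracle dominance, Pareto correctness,
  determinism) is.
* The JSON dialect covers the fields this package uses; exotic
  annotations in deposited files are dropped on conversion.
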
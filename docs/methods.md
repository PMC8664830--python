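# Methods

## Problem and model

Constraint-based analysis treats a metabolic network as a stoichiometric
matrix `S` (m metabolites × r reactions) and studies the feasible steady-state
flux set

```
F = { v | S v = 0,  lb ≤ v ≤ ub } .
```

Condition-specific constraints (measured uptakes, maintenance requirements,
flux-ratio windows) shrink `F`; within that set, some reactions become
coupled so tightly that a *non-negative* linear combination of their fluxes is
forced to a constant. In the language of the resource acquisition–allocation
(Y-)model — traits `X₁ + X₂ = T` drawing on a shared pool `T` — such a
combination is an *absolute* trade-off: since the pool is constant, raising
one member's flux must lower another's. This package identifies and
enumerates all minimal trade-offs of this kind.

The pipeline has two steps.

### Step 1 — classification by flux variability

Flux variability analysis (FVA) minimizes and maximizes every flux over `F`
(2r LPs, no growth-fraction constraint). Each reaction is then

* **blocked** — `|v_min|, |v_max| ≤ tol_zero`;
* **fixed** — `v_max − v_min ≤ tol_fixed · max(1, |v_max|)` and not blocked
  (a reaction constant at zero is blocked, so fixed values are nonzero);
* **fixed-sign variable** — variable with a single sign; non-positive ranges
  are flagged and their columns negated (bounds swapped and negated) so all
  of them carry non-negative flux;
* **sign-variable** — attains both signs. A sign-variable reaction is
  reversible by definition and can be split into two irreversible columns
  without changing the enumerated trade-offs (a property the test suite
  asserts), which justifies excluding it from trade-off candidacy.

Defaults `tol_zero = 1e-9` (absolute) and `tol_fixed = 1e-6` (relative) sit
below typical LP feasibility tolerances and above double-precision noise;
both are exposed in the API and CLI.

### Step 2 — MILP enumeration of minimal trade-offs

A trade-off is a row combination `b = k S` (over real metabolite rows only)
with

* `b_i ≤ 0` for every fixed-sign variable reaction `i` (so `−b_i ≥ 0` are the
  weights of the non-negative combination),
* `b_i = 0` for blocked and sign-variable reactions,
* `Σ b_i ≥ 1` over the fixed reactions (anchoring and normalizing the scale).

For any feasible `v`, `b·v = 0`, hence
`Σ_variable (−b_i) v_i = Σ_fixed b_i v_i = T`: a constant pool shared by the
variable members. With no fixed reactions the anchor constraint is
unsatisfiable and no trade-offs exist.

Minimizing the support of `b` is NP-hard, so the objective is `min ‖b‖₁`,
cast as an LP via `b = b⁺ − b⁻`, `b⁺, b⁻ ≥ 0`. Binary indicators `y_i` for
the fixed-sign variable reactions are linked through
`ε·y_i ≤ −b_i ≤ M·y_i` with `ε = 1e-3` and `M = 1e3` on the normalized scale
(conditioning `M/ε = 1e6`, within MILP integrality tolerances). Enumeration
repeats the solve, after each solution adding the integer cut
`Σ_{i∈S} y_i ≤ |S| − 1` for the found variable support `S`. This cut form
forbids `S` *and all supersets*, so the enumerated supports form an antichain
of minimal trade-offs and the loop terminates (reasons: `infeasible` =
exhausted, `iteration_cap`, `objective_cap` = a solution exceeded the
requested maximum size).

Additional choices:

* `Σ y_i ≥ 1` is imposed so a solution must involve at least one variable
  reaction; without it, two stoichiometrically coupled *fixed* reactions
  admit a degenerate `b` with empty variable support, which is not a
  trade-off.
* Because the L1 objective only approximates support minimality, every MILP
  solution passes a reduction pass: restricted LPs on proper subsets
  (smallest first, up to size 6) replace the support by the smallest feasible
  subset. The reduced support is provably still admissible under all active
  cuts.
* The reported witness (`b`, `k`) is recomputed by a restricted minimum-L1 LP
  on the final support, making reported coefficients independent of the MILP
  search path; `b` and `k` are rescaled so the fixed coefficients sum to
  exactly 1, and entries below `1e-9` snap to zero.
* The steady-state block `S v = 0` printed inside the program above plays no
  role in the optimum (v interacts with neither the objective nor the
  constraints on `b`; the structure of `F` enters through the
  classification), so it is omitted, halving problem size.
* Coefficients on fixed reactions are sign-unconstrained; only their sum is
  bounded below by 1.
* Auxiliary rows added for ratio constraints have their multipliers fixed to
  zero, so trade-offs reflect mass balance only.
* Backend: HiGHS through `scipy.optimize.linprog`/`milp`. HiGHS is
  deterministic for a fixed problem, so enumeration order is reproducible
  without explicit seeding; the configuration seed feeds only the
  flux-sampling validator.

### Validation

`validate_tradeoff` checks each relation three ways: (a) least-squares
residual of `b` against the row space of the real rows of `S`
(≤ `1e-6·‖b‖∞`); (b) `|b·v| ≤ 1e-6·‖b‖₁·‖v‖∞` on `n_samples` feasible flux
vectors obtained by maximizing seeded random objectives over `F`; and (c)
constancy of the pool `Σ_variable (−b_i) v_i = T` on the same samples.

## Constraint recipes

A recipe is a declarative YAML/JSON document with four blocks: `fixed_fluxes`
(sets both bounds), `bound_overrides`, `ratio_constraints`, and
`sequential_fix_to_max`. Ratio windows `r_min ≤ v_num/v_den ≤ r_max`
(admissible only for non-negative fluxes, `0 ≤ r_min ≤ r_max`) are encoded as
two auxiliary rows with non-negative slack columns,
`v_num − r_min v_den − s₁ = 0` and `v_num − r_max v_den + s₂ = 0`, keeping
the whole system in the uniform `S v = 0` form; rows and slacks are tagged
auxiliary and excluded from classification reports and row combinations.
Slack columns get upper bound `1e6` — effectively unbounded relative to
genome-scale flux magnitudes while keeping every LP bounded.
`sequential_fix_to_max` maximizes each listed reaction by FBA **with that
reaction as the objective**, pins it to the attained maximum, and proceeds in
the listed order, recording each derived maximum in the model's
`recipe_log`. Bounds set by a recipe are compared with absolute tolerance
`1e-9` when deciding a reaction was fixed.

## The paradigmatic network

`toy_network()` returns an 8-metabolite, 12-reaction network in which
reactions R3 and R5–R8 are internal and the rest are exchanges; all bounds
are [0, 10] a.u. except R5, fixed to 5. Its stoichiometry (see the function
docstring) was constructed to realize a two-parameter flux cone whose
constrained FVA ranges are

| reaction | range | | reaction | range |
|---|---|---|---|---|
| R1–R4 | [0, 10] | | R9 | [0, 5] |
| R5 | [5, 5] | | R7, R8, R10–R12 | [0, 1.25] |
| R6 | [2.5, 5] | | | |

and whose trade-off structure is fully known: exactly ten minimal trade-offs,
each pairing R6 or R9 with one of {R7, R8, R10, R11, R12} (so R6 and R9 are
the hubs of the co-membership graph), among them `v₅ − v₆ − 2v₈ = 0`, i.e.
`v₆ + 2v₈ = 5`. These over-determining properties are asserted by the test
suite, and the acceptance script recomputes the {R6, R8} relation end to end.

## Benchmark generator

`generate_planted_network` builds random feasible irreversible networks with
known ground truth. Each planted trade-off is a pool metabolite fed by a
bound-fixed uptake (integer coefficients in {1, 2, 3}, fixed values in
{2..6}) and drained by 2–4 variable consumers; a consumer is either a direct
export or an internal conversion followed by an export (probability 0.4),
which plants alternative minimal supports by chain substitution. Extra fixed
reactions feed pass-through chains, and the leftover reaction budget becomes
a random irreversible background (import/export pairs plus random
conversions with coefficients in {1..3}) on metabolites disjoint from the
planted pools — this keeps the planted relations exactly intact, guarantees
feasibility (zero background flux is always admissible), and bounds minimal
support size by 4 so the exhaustive oracle can cap its subset search.
Requested dimensions are upper bounds; the generator stops below the
reaction target rather than disturb a planted pool. Everything derives from
one `numpy` generator seeded by the caller.

What the generator does *not* emulate: realistic network diameter and
cofactor coupling, reversible internal cycles, thermodynamic or enzyme
constraints, and the dense interlocking of genome-scale models. Passing the
benchmark therefore shows correctness of the enumeration machinery
(agreement with exhaustive search, perfect recall of planted structure), not
biological realism of any particular network.

## The exhaustive oracle

`brute_force_tradeoffs` performs the support minimization exactly: for every
subset of fixed-sign variable reactions up to a size cap (guarded so the
subset count stays below 1e6) it solves the restricted LP feasibility problem
and keeps the inclusion-minimal feasible supports, pruning supersets of known
minimal supports before solving. It shares only the constraint definition —
not the search strategy — with the MILP path, so set equality of the two
results on dozens of seeded networks is a meaningful end-to-end check.

## Problem sizes used in the tests

The suite enumerates the toy network once (session fixture) and runs two
50-network benchmark sweeps: one at 10–16 reactions (≤ 15 fixed-sign variable
reactions, oracle cap 4) for oracle equivalence, one at 10–20 reactions for
planted recall with 100-sample validation per trade-off. The whole suite
completes in about two minutes on one CPU.

## Known limitations

* Only *absolute* trade-offs (constant pool `T`) are enumerated; relative
  trade-offs, loopless/thermodynamic variants, and enzyme-constrained model
  extensions are out of scope.
* The support-reduction pass examines subsets up to size 6; a non-minimal
  L1 optimum with a larger true reduction would be reported as found
  (not observed on any tested instance).
* Genome-scale reproduction requires externally downloaded SBML models
  (iJO1366, yeastGEM v8.3.3, AraCore) and is wired as optional integration
  tests activated by placing the files under `models/`.
* SBML is read-only; gene–protein–reaction rules and compartment semantics
  beyond identifier suffixes are ignored.
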
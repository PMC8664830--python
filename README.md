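# fluto

Enumeration of **absolute flux trade-offs** in constraint-based metabolic
models.

Fluxes in a metabolic network compete for shared resources: when condition
constraints (measured uptakes, maintenance requirements, ratio windows) pin
some reactions to fixed values, other fluxes can become coupled so tightly
that a non-negative combination of them is forced to a constant,

```
Σ_variable (−b_i) · v_i  =  T        for every feasible v,
```

so increasing one member's flux must decrease another's — a trade-off in the
sense of the resource acquisition–allocation (Y-)model, *absolute* because
the pool `T` is constant across the whole feasible set. `fluto` finds all
minimal relations of this kind in two steps:

1. **Classification** — flux variability analysis over
   `F = {v | S v = 0, lb ≤ v ≤ ub}` labels every reaction blocked, fixed,
   fixed-sign variable, or sign-variable.
2. **Enumeration** — an L1-minimizing mixed-integer linear program searches
   for row combinations `b = kS` with `b ≤ 0` on fixed-sign variable
   reactions, `b = 0` on blocked/sign-variable ones, and `Σ b ≥ 1` over the
   fixed reactions; integer cuts exclude each found support and its
   supersets, yielding the complete antichain of minimal trade-offs.

The MILP/LP backend is HiGHS (via scipy); SBML models are read through
COBRApy, and a dependency-free JSON dialect covers small fixtures. See
`docs/methods.md` for the formulation, tolerances, and design choices.

## Worked example

```python
import fluto

model = fluto.toy_network()           # 8 metabolites, 12 reactions,
                                      # bounds [0, 10], R5 fixed to 5
fva, cls = fluto.classify_model(model)
print(cls.counts())
# {'blocked': 0, 'fixed': 1, 'fixed_sign_variable': 11, 'sign_variable': 0}

ts = fluto.enumerate_tradeoffs(model, cls)
print(len(ts), ts.size_histogram())
# 10 {2: 10}

for t in ts:
    if t.variable_support == {"R6", "R8"}:
        print({rid: t.coefficient(model, rid)
               for rid in sorted(t.variable_support | t.fixed_support)},
              "T =", t.constant_T)
# {'R5': 1.0, 'R6': -1.0, 'R8': -2.0} T = 5.0
```

The printed relation reads `v5 − v6 − 2·v8 = 0`: because R5 is fixed to 5,
every feasible flux distribution satisfies `v6 + 2·v8 = 5`, a two-reaction
trade-off between R6 and R8 drawing on a pool of constant size 5. The toy
network carries ten such pairwise trade-offs, and reactions R6 and R9
participate in the most of them (five each) — visible in the co-membership
graph:

```python
graph = fluto.build_tradeoff_graph(ts)
print(sorted(graph.degree, key=lambda kv: -kv[1])[:2])
# [('R6', 5), ('R9', 5)]
```

Every enumerated relation can be checked against sampled feasible fluxes:

```python
report = fluto.validate_tradeoff(t, model, n_samples=100, seed=1)
print(report.ok)   # True: b·v = 0 and the pool is constant on all samples
```

## Command line

```sh
fluto classify  --model toy.json --out-dir out/       # FVA + categories
fluto enumerate --model toy.json --out-dir out/       # trade-offs (TSV/JSON)
fluto validate  --model toy.json --tradeoffs out/tradeoffs.json
fluto graph     --model toy.json --tradeoffs out/tradeoffs.json --out-dir out/
fluto generate  --seed 7 --out-dir out/               # planted benchmark
fluto summarize --model toy.json --label glucose --out-dir out/
```

Recipes (`--recipe recipe.yaml`) declare fixed fluxes, bound overrides,
flux-ratio windows, and sequential fix-to-maximum steps:

```yaml
fixed_fluxes: {EX_glc__D_e: -10.0}
ratio_constraints: [[sucrose_export, starch_export, 2.5, 4.0]]
sequential_fix_to_max: [ATPS4rpp, EX_pi_e]
```

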
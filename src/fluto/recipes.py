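"""Constraint recipes: declarative flux constraints applied to a model.

A recipe collects the condition-specific constraints used before trade-off
analysis: fixed uptake/maintenance fluxes, bound overrides, flux-ratio
constraints (e.g. sucrose:starch between 2.5 and 4), and a sequential
fix-to-maximum procedure in which listed reactions are maximized one at a time
by FBA and then pinned to the attained optimum.  The last of these is how
condition constraints such as a maximum phosphate uptake are derived from
rounds of FBA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ._lp import solve_lp
from .model import MetabolicModel, ModelValidationError

#: absolute tolerance when deciding that a recipe fixed a reaction
BOUND_EQUAL_ATOL = 1e-9

#: upper bound given to ratio slack columns; effectively unbounded relative to
#: the flux scale of genome-scale models while keeping every LP bounded
SLACK_UB = 1e6


class RecipeError(ValueError):
    """Recipe refers to missing reactions or is internally inconsistent."""


class InfeasibleStepError(RuntimeError):
    """A sequential fix-to-max step had no feasible FBA solution."""


@dataclass
class RatioConstraint:
    """``min_ratio <= v_num / v_den <= max_ratio`` for non-negative fluxes,
    encoded linearly as ``v_num - min_ratio*v_den >= 0`` and
    ``v_num - max_ratio*v_den <= 0``."""
    numerator: str
    denominator: str
    min_ratio: float
    max_ratio: float


@dataclass
class ConstraintRecipe:
    fixed_fluxes: dict[str, float] = field(default_factory=dict)
    bound_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    ratio_constraints: list[RatioConstraint] = field(default_factory=list)
    sequential_fix_to_max: list[str] = field(default_factory=list)

    @classmethod
    def from_dict(cls, data: dict) -> "ConstraintRecipe":
        ratios = [RatioConstraint(*r) if not isinstance(r, RatioConstraint)
                  else r for r in data.get("ratio_constraints", [])]
        return cls(
            fixed_fluxes={k: float(v)
                          for k, v in data.get("fixed_fluxes", {}).items()},
            bound_overrides={k: (float(v[0]), float(v[1]))
                             for k, v in data.get("bound_overrides", {}).items()},
            ratio_constraints=ratios,
            sequential_fix_to_max=list(data.get("sequential_fix_to_max", [])),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "ConstraintRecipe":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        return cls.from_dict(data or {})


def fba_optimize(model: MetabolicModel, objective: str | np.ndarray,
                 sense: str = "max") -> float:
    """Flux balance analysis: optimize a flux objective over
    ``S v = 0, lb <= v <= ub`` and return the optimum.

    ``objective`` is a reaction id (single-flux objective) or a per-reaction
    coefficient vector.
    """
    if isinstance(objective, str):
        c = np.zeros(model.n_reactions)
        c[model.reaction_index(objective)] = 1.0
    else:
        c = np.asarray(objective, dtype=float)
    sign = -1.0 if sense == "max" else 1.0
    res = solve_lp(sign * c, A_eq=model.S, b_eq=np.zeros(model.n_metabolites),
                   bounds=list(zip(model.lower_bounds, model.upper_bounds)))
    if not res.optimal:
        raise InfeasibleStepError(f"FBA problem is {res.status}")
    return sign * res.fun


def _check_ids(model: MetabolicModel, recipe: ConstraintRecipe) -> None:
    known = set(model.reaction_ids)
    referenced = (set(recipe.fixed_fluxes) | set(recipe.bound_overrides)
                  | set(recipe.sequential_fix_to_max)
                  | {r.numerator for r in recipe.ratio_constraints}
                  | {r.denominator for r in recipe.ratio_constraints})
    missing = sorted(referenced - known)
    if missing:
        raise RecipeError(f"recipe references unknown reactions: {missing}")


def apply_recipe(model: MetabolicModel,
                 recipe: ConstraintRecipe) -> MetabolicModel:
    """Return a new model with the recipe applied.

    Fixed fluxes set both bounds, overrides replace bounds, ratio constraints
    are appended as auxiliary rows of ``S`` with slack columns (so ``S v = 0``
    still encodes them), and each reaction in ``sequential_fix_to_max`` is
    maximized by FBA (with itself as the objective) and pinned to the attained
    maximum, in the listed order.  Derived maxima are recorded in
    ``model.notes["recipe_log"]``.
    """
    _check_ids(model, recipe)
    out = model.copy()
    log: list[dict] = []

    for rid, value in recipe.fixed_fluxes.items():
        j = out.reaction_index(rid)
        out.lower_bounds[j] = out.upper_bounds[j] = float(value)
        log.append({"step": "fix", "reaction": rid, "value": float(value)})

    for rid, (lb, ub) in recipe.bound_overrides.items():
        if lb > ub:
            raise RecipeError(f"override for {rid!r} has lb > ub")
        j = out.reaction_index(rid)
        out.lower_bounds[j], out.upper_bounds[j] = lb, ub
        log.append({"step": "bounds", "reaction": rid, "lb": lb, "ub": ub})

    for n, ratio in enumerate(recipe.ratio_constraints):
        if not (0 <= ratio.min_ratio <= ratio.max_ratio):
            raise RecipeError(
                f"ratio constraint {ratio.numerator}/{ratio.denominator}: "
                "need 0 <= min_ratio <= max_ratio")
        for rid in (ratio.numerator, ratio.denominator):
            if out.lower_bounds[out.reaction_index(rid)] < 0:
                raise ModelValidationError(
                    f"ratio constraint on reaction {rid!r} with negative "
                    "admissible flux")
        out = _append_ratio_rows(out, ratio, n)
        log.append({"step": "ratio", "numerator": ratio.numerator,
                    "denominator": ratio.denominator,
                    "min_ratio": ratio.min_ratio, "max_ratio": ratio.max_ratio})

    for rid in recipe.sequential_fix_to_max:
        try:
            vmax = fba_optimize(out, rid, sense="max")
        except InfeasibleStepError as exc:
            raise InfeasibleStepError(
                f"sequential fix-to-max step for {rid!r} failed: {exc}"
            ) from exc
        j = out.reaction_index(rid)
        out.lower_bounds[j] = out.upper_bounds[j] = vmax
        log.append({"step": "fix_to_max", "reaction": rid, "value": vmax})

    out.notes.setdefault("recipe_log", []).extend(log)
    return out


def _append_ratio_rows(model: MetabolicModel, ratio: RatioConstraint,
                       n: int) -> MetabolicModel:
    """Append two auxiliary rows + slack columns encoding the ratio window."""
    jn = model.reaction_index(ratio.numerator)
    jd = model.reaction_index(ratio.denominator)
    m, r = model.n_metabolites, model.n_reactions
    tag = f"{ratio.numerator}__{ratio.denominator}__{n}"
    row_ids = [f"_ratio_min_{tag}", f"_ratio_max_{tag}"]
    slack_ids = [f"_slack_min_{tag}", f"_slack_max_{tag}"]
    S = np.zeros((m + 2, r + 2))
    S[:m, :r] = model.S
    # v_num - min_ratio*v_den - s1 = 0, s1 >= 0  <=>  ratio >= min_ratio
    S[m, jn], S[m, jd], S[m, r] = 1.0, -ratio.min_ratio, -1.0
    # v_num - max_ratio*v_den + s2 = 0, s2 >= 0  <=>  ratio <= max_ratio
    S[m + 1, jn], S[m + 1, jd], S[m + 1, r + 1] = 1.0, -ratio.max_ratio, 1.0
    return MetabolicModel(
        metabolite_ids=model.metabolite_ids + row_ids,
        reaction_ids=model.reaction_ids + slack_ids,
        S=S,
        lower_bounds=np.concatenate([model.lower_bounds, [0.0, 0.0]]),
        upper_bounds=np.concatenate([model.upper_bounds, [SLACK_UB, SLACK_UB]]),
        subsystems=model.subsystems + [[], []],
        objective_coefficients=None if model.objective_coefficients is None
        else np.concatenate([model.objective_coefficients, [0.0, 0.0]]),
        auxiliary_metabolites=model.auxiliary_metabolites | set(row_ids),
        auxiliary_reactions=model.auxiliary_reactions | set(slack_ids),
        notes=dict(model.notes),
    )
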
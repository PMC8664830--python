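"""Step 1: flux variability analysis and reaction categorization.

Every reaction is classified by its attainable flux range over the feasible
set ``F = {v | S v = 0, lb <= v <= ub}``:

* **blocked** — carries no flux in any feasible distribution;
* **fixed** — carries one constant non-zero flux (a reaction constant at zero
  is blocked by convention);
* **fixed_sign_variable** — variable flux of a single sign; non-positive
  ranges are marked ``flipped`` so the sign convention can be made
  non-negative by negating the column;
* **sign_variable** — variable flux attaining both signs.

Trade-offs can only involve fixed-sign variable reactions (anchored by fixed
ones), so this classification is the input to the enumeration step.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._lp import INFEASIBLE, solve_lp
from .model import MetabolicModel

BLOCKED = "blocked"
FIXED = "fixed"
FIXED_SIGN_VARIABLE = "fixed_sign_variable"
SIGN_VARIABLE = "sign_variable"
CATEGORIES = (BLOCKED, FIXED, FIXED_SIGN_VARIABLE, SIGN_VARIABLE)

DEFAULT_TOL_ZERO = 1e-9
DEFAULT_TOL_FIXED = 1e-6


class InfeasibleModelError(RuntimeError):
    """The model admits no steady-state flux distribution."""


@dataclass
class FvaResult:
    """Per-reaction minimum/maximum steady-state flux."""

    reaction_ids: list[str]
    v_min: np.ndarray
    v_max: np.ndarray
    #: reactions whose min/max LP was unbounded (range reported at the bound)
    unbounded: np.ndarray = None

    def __post_init__(self):
        if self.unbounded is None:
            self.unbounded = np.zeros(len(self.reaction_ids), dtype=bool)

    def range_of(self, rid: str) -> tuple[float, float]:
        j = self.reaction_ids.index(rid)
        return float(self.v_min[j]), float(self.v_max[j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"reaction_id": self.reaction_ids,
                             "v_min": self.v_min, "v_max": self.v_max})


@dataclass
class ReactionClassification:
    """Category per reaction, with fixed values and sign-flip flags."""

    reaction_ids: list[str]
    category: list[str]
    fixed_value: dict[str, float] = field(default_factory=dict)
    flipped: np.ndarray = None

    def __post_init__(self):
        if self.flipped is None:
            self.flipped = np.zeros(len(self.reaction_ids), dtype=bool)

    def category_of(self, rid: str) -> str:
        return self.category[self.reaction_ids.index(rid)]

    def ids_in(self, category: str) -> list[str]:
        return [rid for rid, c in zip(self.reaction_ids, self.category)
                if c == category]

    def counts(self) -> dict[str, int]:
        return {c: self.category.count(c) for c in CATEGORIES}


def run_fva(model: MetabolicModel) -> FvaResult:
    """Minimize and maximize each reaction flux over the constrained feasible
    set (no growth-fraction constraint; plain FVA over all of ``F``).

    Raises :class:`InfeasibleModelError` before any per-reaction solve if the
    model is infeasible.  If a direction is unbounded the range endpoint is
    reported at the model bound and the reaction is flagged.
    """
    r = model.n_reactions
    beq = np.zeros(model.n_metabolites)
    bounds = list(zip(
        (None if np.isneginf(l) else l for l in model.lower_bounds),
        (None if np.isposinf(u) else u for u in model.upper_bounds)))
    probe = solve_lp(np.zeros(r), A_eq=model.S, b_eq=beq, bounds=bounds)
    if probe.status == INFEASIBLE:
        raise InfeasibleModelError(
            "model admits no steady-state flux distribution")

    v_min = np.empty(r)
    v_max = np.empty(r)
    unbounded = np.zeros(r, dtype=bool)
    c = np.zeros(r)
    for j in range(r):
        c[j] = 1.0
        lo = solve_lp(c, A_eq=model.S, b_eq=beq, bounds=bounds)
        c[j] = -1.0
        hi = solve_lp(c, A_eq=model.S, b_eq=beq, bounds=bounds)
        c[j] = 0.0
        if lo.optimal:
            v_min[j] = lo.fun
        else:  # unbounded below: report at the (infinite) model bound
            v_min[j] = model.lower_bounds[j]
            unbounded[j] = True
        if hi.optimal:
            v_max[j] = -hi.fun
        else:
            v_max[j] = model.upper_bounds[j]
            unbounded[j] = True
    return FvaResult(list(model.reaction_ids), v_min, v_max, unbounded)


def classify_reactions(fva: FvaResult,
                       tol_fixed: float = DEFAULT_TOL_FIXED,
                       tol_zero: float = DEFAULT_TOL_ZERO,
                       ) -> ReactionClassification:
    """Categorize each reaction from its FVA range.

    ``tol_zero`` is the absolute tolerance for "no flux"; ``tol_fixed`` is the
    relative tolerance for "constant flux".  Ranges with an endpoint exactly
    at zero resolve toward fixed-sign variable.
    """
    categories: list[str] = []
    fixed_value: dict[str, float] = {}
    flipped = np.zeros(len(fva.reaction_ids), dtype=bool)
    for j, rid in enumerate(fva.reaction_ids):
        lo, hi = fva.v_min[j], fva.v_max[j]
        if abs(lo) <= tol_zero and abs(hi) <= tol_zero:
            categories.append(BLOCKED)
        elif hi - lo <= tol_fixed * max(1.0, abs(hi)):
            categories.append(FIXED)
            fixed_value[rid] = (lo + hi) / 2.0
        elif lo >= -tol_zero or hi <= tol_zero:
            categories.append(FIXED_SIGN_VARIABLE)
            flipped[j] = hi <= tol_zero
        else:
            categories.append(SIGN_VARIABLE)
    return ReactionClassification(list(fva.reaction_ids), categories,
                                  fixed_value, flipped)


def flip_signs(model: MetabolicModel,
               classification: ReactionClassification) -> MetabolicModel:
    """Negate the columns of flipped reactions so every fixed-sign variable
    reaction carries non-negative flux; bounds are negated and swapped."""
    out = model.copy()
    for j, rid in enumerate(classification.reaction_ids):
        if not classification.flipped[j]:
            continue
        jj = out.reaction_index(rid)
        out.S[:, jj] = -out.S[:, jj]
        lb, ub = out.lower_bounds[jj], out.upper_bounds[jj]
        out.lower_bounds[jj], out.upper_bounds[jj] = -ub, -lb
        if rid in classification.fixed_value:
            classification.fixed_value[rid] = -classification.fixed_value[rid]
    return out


def classify_model(model: MetabolicModel,
                   tol_fixed: float = DEFAULT_TOL_FIXED,
                   tol_zero: float = DEFAULT_TOL_ZERO,
                   ) -> tuple[FvaResult, ReactionClassification]:
    """Convenience wrapper: FVA followed by categorization."""
    fva = run_fva(model)
    return fva, classify_reactions(fva, tol_fixed, tol_zero)


def write_fva_tsv(fva: FvaResult, classification: ReactionClassification,
                  path: str | Path) -> None:
    """Export FVA ranges and categories as TSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["reaction_id", "v_min", "v_max", "category",
                         "flipped"])
        for j, rid in enumerate(fva.reaction_ids):
            writer.writerow([rid, repr(float(fva.v_min[j])),
                             repr(float(fva.v_max[j])),
                             classification.category[j],
                             str(bool(classification.flipped[j])).lower()])
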
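"""In-memory representation of a stoichiometric metabolic model and file I/O.

A model is the matrix ``S`` (metabolites x reactions) together with per-reaction
flux bounds and optional annotations.  Steady state requires ``S v = 0``; the
feasible flux set is ``F = {v | S v = 0, lb <= v <= ub}``.

Two formats are supported: SBML Level 3 with the FBC package (read through
COBRApy, read-only) and a minimal JSON dialect used for fixtures::

    {"metabolites": ["A", ...],
     "reactions": [{"id": "R1", "stoichiometry": {"A": -1.0, ...},
                    "lb": 0.0, "ub": 10.0, "subsystems": ["glycolysis"]}, ...]}

Ratio constraints (see :mod:`fluto.recipes`) are encoded as *auxiliary* rows of
``S`` with slack columns so that every module sees one uniform ``S v = 0``
system; auxiliary rows and columns are tagged and excluded from trade-off
row combinations and from classification reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class ModelFormatError(ValueError):
    """Malformed model file (parse failure, missing or bad element)."""


class ModelValidationError(ValueError):
    """Structurally invalid model (duplicate ids, bound violations, ...)."""


@dataclass(eq=False)
class MetabolicModel:
    """A stoichiometric model with flux bounds.

    Parameters
    ----------
    metabolite_ids, reaction_ids
        Unique identifiers for the rows and columns of ``S``.
    S
        Dense ``(m, r)`` array of stoichiometric coefficients.
    lower_bounds, upper_bounds
        Per-reaction flux bounds (mmol gDW^-1 h^-1 for genome-scale models,
        arbitrary units for toys).
    subsystems
        Per-reaction list of zero or more pathway labels.
    objective_coefficients
        Optional per-reaction objective weights (used by FBA helpers).
    auxiliary_metabolites, auxiliary_reactions
        Identifiers of pseudo-rows/columns added to encode ratio constraints.
        They take part in ``S v = 0`` but are excluded from mass-balance
        row combinations and from reaction classification reports.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    subsystems: list[list[str]] | None = None
    objective_coefficients: np.ndarray | None = None
    auxiliary_metabolites: set[str] = field(default_factory=set)
    auxiliary_reactions: set[str] = field(default_factory=set)
    notes: dict = field(default_factory=dict)

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        if self.subsystems is None:
            self.subsystems = [[] for _ in self.reaction_ids]
        m, r = len(self.metabolite_ids), len(self.reaction_ids)
        if self.S.shape != (m, r):
            raise ModelValidationError(
                f"S has shape {self.S.shape}, expected ({m}, {r})")
        for name, ids in (("metabolite", self.metabolite_ids),
                          ("reaction", self.reaction_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise ModelValidationError(f"duplicate {name} ids: {dupes}")
        if self.lower_bounds.shape != (r,) or self.upper_bounds.shape != (r,):
            raise ModelValidationError("bounds must be per-reaction vectors")
        bad = np.nonzero(self.lower_bounds > self.upper_bounds)[0]
        if bad.size:
            raise ModelValidationError(
                f"lower bound exceeds upper bound for "
                f"{[self.reaction_ids[i] for i in bad]}")
        if len(self.subsystems) != r:
            raise ModelValidationError("subsystems must be per-reaction")
        self._met_index = {mid: i for i, mid in enumerate(self.metabolite_ids)}
        self._rxn_index = {rid: j for j, rid in enumerate(self.reaction_ids)}

    # -- lookups ---------------------------------------------------------

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def metabolite_index(self, met_id: str) -> int:
        try:
            return self._met_index[met_id]
        except KeyError:
            raise KeyError(f"unknown metabolite id {met_id!r}") from None

    def reaction_index(self, rxn_id: str) -> int:
        try:
            return self._rxn_index[rxn_id]
        except KeyError:
            raise KeyError(f"unknown reaction id {rxn_id!r}") from None

    @property
    def structural_row_mask(self) -> np.ndarray:
        """Boolean mask of real (non-auxiliary) metabolite rows."""
        return np.array([mid not in self.auxiliary_metabolites
                         for mid in self.metabolite_ids], dtype=bool)

    @property
    def structural_reaction_mask(self) -> np.ndarray:
        """Boolean mask of real (non-slack) reaction columns."""
        return np.array([rid not in self.auxiliary_reactions
                         for rid in self.reaction_ids], dtype=bool)

    @property
    def exchange_flags(self) -> np.ndarray:
        """Per-reaction boolean: column touches exactly one structural row."""
        sub = self.S[self.structural_row_mask, :]
        return (np.count_nonzero(sub, axis=0) == 1) & self.structural_reaction_mask

    # -- manipulation ----------------------------------------------------

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            S=self.S.copy(),
            lower_bounds=self.lower_bounds.copy(),
            upper_bounds=self.upper_bounds.copy(),
            subsystems=[list(s) for s in self.subsystems],
            objective_coefficients=None if self.objective_coefficients is None
            else self.objective_coefficients.copy(),
            auxiliary_metabolites=set(self.auxiliary_metabolites),
            auxiliary_reactions=set(self.auxiliary_reactions),
            notes=dict(self.notes),
        )

    def equals(self, other: "MetabolicModel", tol: float = 0.0) -> bool:
        """Equality up to row/column permutation of ``S`` (ids matched)."""
        if (set(self.metabolite_ids) != set(other.metabolite_ids)
                or set(self.reaction_ids) != set(other.reaction_ids)):
            return False
        rows = [other.metabolite_index(m) for m in self.metabolite_ids]
        cols = [other.reaction_index(r) for r in self.reaction_ids]
        S2 = other.S[np.ix_(rows, cols)]
        lb2 = other.lower_bounds[cols]
        ub2 = other.upper_bounds[cols]
        return (np.allclose(self.S, S2, atol=tol)
                and np.allclose(self.lower_bounds, lb2, atol=tol)
                and np.allclose(self.upper_bounds, ub2, atol=tol))


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def _model_from_json_dict(data: dict) -> MetabolicModel:
    if not isinstance(data, dict) or "metabolites" not in data or \
            "reactions" not in data:
        raise ModelFormatError(
            "JSON model must be an object with 'metabolites' and 'reactions'")
    met_ids = list(data["metabolites"])
    if not all(isinstance(m, str) for m in met_ids):
        raise ModelFormatError("'metabolites' must be a list of id strings")
    rxn_ids, lbs, ubs, subsystems = [], [], [], []
    met_set = set(met_ids)
    S = np.zeros((len(met_ids), len(data["reactions"])))
    for j, rxn in enumerate(data["reactions"]):
        for key in ("id", "stoichiometry", "lb", "ub"):
            if key not in rxn:
                raise ModelFormatError(
                    f"reaction #{j} is missing required key {key!r}")
        rxn_ids.append(rxn["id"])
        for met, coeff in rxn["stoichiometry"].items():
            if met not in met_set:
                raise ModelFormatError(
                    f"reaction {rxn['id']!r} references unknown metabolite "
                    f"{met!r}")
            S[met_ids.index(met), j] = float(coeff)
        lbs.append(float(rxn["lb"]))
        ubs.append(float(rxn["ub"]))
        subsystems.append(list(rxn.get("subsystems", [])))
    try:
        return MetabolicModel(met_ids, rxn_ids, S, np.array(lbs),
                              np.array(ubs), subsystems)
    except ModelValidationError:
        raise


def read_json_model(path: str | Path) -> MetabolicModel:
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path} is not valid JSON: {exc}") from exc
    return _model_from_json_dict(data)


def write_model(model: MetabolicModel, path: str | Path) -> None:
    """Write a model in the JSON dialect (auxiliary rows are not exported)."""
    smask = model.structural_row_mask
    rmask = model.structural_reaction_mask
    mets = [m for m, keep in zip(model.metabolite_ids, smask) if keep]
    rxns = []
    for j, rid in enumerate(model.reaction_ids):
        if not rmask[j]:
            continue
        stoich = {model.metabolite_ids[i]: model.S[i, j]
                  for i in np.nonzero(model.S[:, j])[0] if smask[i]}
        rxns.append({
            "id": rid,
            "stoichiometry": stoich,
            "lb": model.lower_bounds[j],
            "ub": model.upper_bounds[j],
            "subsystems": model.subsystems[j],
        })
    Path(path).write_text(
        json.dumps({"metabolites": mets, "reactions": rxns}, indent=1))


# ---------------------------------------------------------------------------
# SBML (read-only, through COBRApy)
# ---------------------------------------------------------------------------

def read_sbml_model(path: str | Path) -> MetabolicModel:
    import cobra.io
    from cobra.util.array import create_stoichiometric_matrix

    try:
        cmodel = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # libsbml raises a zoo of types
        raise ModelFormatError(f"failed to parse SBML file {path}: {exc}") from exc
    S = create_stoichiometric_matrix(cmodel, array_type="dense")
    met_ids = [m.id for m in cmodel.metabolites]
    rxn_ids = [r.id for r in cmodel.reactions]
    lbs = np.array([r.lower_bound for r in cmodel.reactions], dtype=float)
    ubs = np.array([r.upper_bound for r in cmodel.reactions], dtype=float)
    subsystems = [[r.subsystem] if r.subsystem else [] for r in cmodel.reactions]
    objective = np.array([r.objective_coefficient for r in cmodel.reactions],
                         dtype=float)
    if not objective.any():
        objective = None
    return MetabolicModel(met_ids, rxn_ids, S, lbs, ubs, subsystems, objective)


def read_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Read a model from ``path``; ``format`` is ``"sbml"``, ``"json"`` or
    ``None`` to infer from the file extension."""
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "json"
    if format == "json":
        return read_json_model(path)
    if format == "sbml":
        return read_sbml_model(path)
    raise ValueError(f"unknown model format {format!r}")
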
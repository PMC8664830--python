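import json

import numpy as np
import pytest

from fluto import (ConstraintRecipe, MetabolicModel, RatioConstraint,
                   apply_recipe, read_model, run_fva, toy_network, write_model)
from fluto.model import ModelFormatError, ModelValidationError
from fluto.recipes import RecipeError


def test_json_round_trip_preserves_model(toy_model, tmp_path):
    path = tmp_path / "toy.json"
    write_model(toy_model, path)
    again = read_model(path)
    assert again.equals(toy_model)
    assert again.n_metabolites == 8 and again.n_reactions == 12


def test_single_exchange_model_round_trips(tmp_path):
    model = MetabolicModel(["A"], ["EX_A"], np.array([[1.0]]),
                           np.array([0.0]), np.array([0.0]))
    path = tmp_path / "one.json"
    write_model(model, path)
    assert read_model(path).equals(model)


def test_format_errors_name_the_offending_element(tmp_path):
    bad = tmp_path / "bad.json"
    bad.write_text('{"metabolites": ["A"], "reactions": [{"id": "R1", '
                   '"stoichiometry": {"ZZZ": 1}, "lb": 0, "ub": 1}]}')
    with pytest.raises(ModelFormatError, match="ZZZ"):
        read_model(bad)
    notjson = tmp_path / "garbled.json"
    notjson.write_text("{not json")
    with pytest.raises(ModelFormatError):
        read_model(notjson)


def test_duplicate_identifiers_rejected():
    with pytest.raises(ModelValidationError, match="duplicate"):
        MetabolicModel(["A", "A"], ["R1"], np.zeros((2, 1)),
                       np.zeros(1), np.ones(1))
    with pytest.raises(ModelValidationError, match="lower bound"):
        MetabolicModel(["A"], ["R1"], np.zeros((1, 1)),
                       np.array([2.0]), np.array([1.0]))


def test_sbml_read_matches_source_model(toy_model, tmp_path):
    cobra = pytest.importorskip("cobra")
    from conftest import to_cobra

    path = tmp_path / "toy.xml"
    cobra.io.write_sbml_model(to_cobra(toy_model), str(path))
    model = read_model(path, format="sbml")
    assert model.equals(toy_model)


class TestApplyRecipe:
    def test_fixed_flux_sets_both_bounds(self, toy_model):
        out = apply_recipe(toy_model,
                           ConstraintRecipe(fixed_fluxes={"R5": 5.0}))
        j = out.reaction_index("R5")
        assert out.lower_bounds[j] == out.upper_bounds[j] == 5.0

    def test_empty_recipe_is_identity(self, toy_model):
        assert apply_recipe(toy_model, ConstraintRecipe()).equals(toy_model)

    def test_idempotent_for_fixes_and_overrides(self, toy_model):
        recipe = ConstraintRecipe(fixed_fluxes={"R9": 2.0},
                                  bound_overrides={"R7": (0.0, 1.0)})
        once = apply_recipe(toy_model, recipe)
        twice = apply_recipe(once, recipe)
        assert twice.equals(once)

    def test_unknown_reaction_rejected(self, toy_model):
        with pytest.raises(RecipeError, match="NOPE"):
            apply_recipe(toy_model, ConstraintRecipe(fixed_fluxes={"NOPE": 1}))

    def test_recipe_loads_from_yaml(self, toy_model, tmp_path):
        path = tmp_path / "recipe.yaml"
        path.write_text(
            "fixed_fluxes: {R5: 5.0}\n"
            "bound_overrides: {R7: [0.0, 1.0]}\n"
            "ratio_constraints: [[R6, R9, 1.5, 4.0]]\n"
            "sequential_fix_to_max: [R9]\n")
        recipe = ConstraintRecipe.from_file(path)
        assert recipe.fixed_fluxes == {"R5": 5.0}
        assert recipe.ratio_constraints[0] == RatioConstraint("R6", "R9",
                                                              1.5, 4.0)
        assert recipe.sequential_fix_to_max == ["R9"]


class TestRatioConstraints:
    def test_ratio_window_restricts_fva(self, toy_model):
        # v6 = 5 - 2s, v9 = 5 - 4s; 1.5 <= v6/v9 <= 4 pins s to
        # [0.625, 15/14], which shows up in the range of v7 (= s)
        recipe = ConstraintRecipe(
            ratio_constraints=[RatioConstraint("R6", "R9", 1.5, 4.0)])
        out = apply_recipe(toy_model, recipe)
        fva = run_fva(out)
        lo, hi = fva.range_of("R7")
        assert lo == pytest.approx(0.625, abs=1e-6)
        assert hi == pytest.approx(15 / 14, abs=1e-6)

    def test_auxiliary_rows_are_tagged(self, toy_model):
        out = apply_recipe(toy_model, ConstraintRecipe(
            ratio_constraints=[RatioConstraint("R6", "R9", 1.5, 4.0)]))
        assert len(out.auxiliary_metabolites) == 2
        assert len(out.auxiliary_reactions) == 2
        # real metabolite rows untouched
        mask = out.structural_row_mask
        assert np.array_equal(out.S[mask][:, :12], toy_model.S)

    def test_invalid_ratio_rejected(self, toy_model):
        with pytest.raises(RecipeError):
            apply_recipe(toy_model, ConstraintRecipe(
                ratio_constraints=[RatioConstraint("R6", "R9", 4.0, 1.5)]))

    def test_ratio_on_reversible_reaction_rejected(self, toy_model):
        model = toy_model.copy()
        model.lower_bounds[model.reaction_index("R9")] = -10.0
        with pytest.raises(ModelValidationError, match="negative"):
            apply_recipe(model, ConstraintRecipe(
                ratio_constraints=[RatioConstraint("R6", "R9", 1.5, 4.0)]))


class TestSequentialFixToMax:
    def test_maxima_match_independent_fba(self, toy_model):
        """Each step's derived maximum equals COBRApy's FBA optimum."""
        cobra = pytest.importorskip("cobra")
        from conftest import to_cobra

        order = ["R9", "R7"]
        recipe = ConstraintRecipe(sequential_fix_to_max=order)
        out = apply_recipe(toy_model, recipe)
        log = [e for e in out.notes["recipe_log"]
               if e["step"] == "fix_to_max"]

        cm = to_cobra(toy_model)
        expected = {}
        for rid in order:
            cm.objective = rid
            vmax = cm.optimize().objective_value
            expected[rid] = vmax
            rxn = cm.reactions.get_by_id(rid)
            rxn.lower_bound = rxn.upper_bound = vmax
        for entry in log:
            assert entry["value"] == pytest.approx(
                expected[entry["reaction"]], abs=1e-6)
        # maximizing R9 (-> 5) forces the branch flux s to 0, so R7 max is 0
        assert dict((e["reaction"], round(e["value"], 6)) for e in log) == \
            {"R9": 5.0, "R7": 0.0}

    def test_infeasible_step_identifies_reaction(self, toy_model):
        from fluto.recipes import InfeasibleStepError

        model = toy_model.copy()
        j = model.reaction_index("R6")  # demand R6 > its attainable max
        model.lower_bounds[j] = 8.0
        with pytest.raises(InfeasibleStepError, match="R9"):
            apply_recipe(model,
                         ConstraintRecipe(sequential_fix_to_max=["R9"]))
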
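import numpy as np
import pytest

import fluto
from fluto import (enumerate_tradeoffs, find_tradeoff, normalize_tradeoff,
                   validate_tradeoff)
from fluto._lp import solve_lp
from fluto.tradeoffs import TradeOff, tradeoffs_from_json, tradeoffs_to_json


def relation_of(tradeoffs, model, support):
    """Pick the trade-off with the given variable support as a coefficient
    map over its participating reactions."""
    for t in tradeoffs:
        if t.variable_support == frozenset(support):
            return {rid: t.coefficient(model, rid)
                    for rid in t.variable_support | t.fixed_support}
    raise AssertionError(f"no trade-off with support {support}")


def test_first_tradeoff_is_a_printed_pair(toy_model, toy_classification):
    to = find_tradeoff(toy_model, toy_classification)
    assert to is not None and to.size == 2
    assert to.fixed_support == {"R5"}


def test_toy_relation_links_r6_r8_to_r5(toy_model, toy_tradeoffs):
    rel = relation_of(toy_tradeoffs, toy_model, {"R6", "R8"})
    assert rel == pytest.approx({"R5": 1.0, "R6": -1.0, "R8": -2.0},
                                abs=1e-8)


def test_pool_constant_equals_fixed_flux(toy_model, toy_tradeoffs):
    for t in toy_tradeoffs:
        assert t.constant_T == pytest.approx(5.0, abs=1e-8)


def test_without_fixed_reactions_no_tradeoffs(toy_model):
    model = toy_model.copy()
    j = model.reaction_index("R5")
    model.lower_bounds[j], model.upper_bounds[j] = 0.0, 10.0
    fva, cls = fluto.classify_model(model)
    assert cls.counts()["fixed"] == 0
    assert find_tradeoff(model, cls) is None
    ts = enumerate_tradeoffs(model, cls)
    assert len(ts) == 0 and ts.termination_reason == "infeasible"


def test_supports_form_an_antichain(toy_tradeoffs):
    sups = toy_tradeoffs.supports()
    assert len(set(sups)) == len(sups)
    for a in sups:
        for b in sups:
            assert a == b or not a < b


def test_b_is_orthogonal_to_the_feasible_set(toy_model, toy_tradeoffs):
    """max and min of b.v over F are both ~0 for every trade-off."""
    bounds = list(zip(toy_model.lower_bounds, toy_model.upper_bounds))
    beq = np.zeros(toy_model.n_metabolites)
    for t in toy_tradeoffs:
        for sign in (1.0, -1.0):
            res = solve_lp(sign * t.b, A_eq=toy_model.S, b_eq=beq,
                           bounds=bounds)
            assert res.optimal and abs(res.fun) < 1e-7


def test_row_space_membership(toy_model, toy_tradeoffs):
    for t in toy_tradeoffs:
        assert np.allclose(t.k @ toy_model.S, t.b, atol=1e-8)


def test_iteration_cap_terminates_early(toy_model, toy_classification):
    ts = enumerate_tradeoffs(toy_model, toy_classification, max_iterations=3)
    assert len(ts) == 3 and ts.termination_reason == "iteration_cap"


class TestValidate:
    def test_toy_relation_pool_is_constant(self, toy_model, toy_tradeoffs):
        rel = next(t for t in toy_tradeoffs
                   if t.variable_support == {"R6", "R8"})
        report = validate_tradeoff(rel, toy_model, n_samples=50, seed=11)
        assert report.ok
        # v6 + 2 v8 = 5 on every sampled flux distribution
        assert np.allclose(report.constant_values, 5.0, atol=1e-6)

    def test_zero_vector_rejected(self, toy_model, toy_tradeoffs):
        t = toy_tradeoffs.tradeoffs[0]
        degenerate = TradeOff(b=np.zeros_like(t.b), k=np.zeros_like(t.k),
                              variable_support=frozenset(),
                              fixed_support=frozenset(), constant_T=0.0)
        with pytest.raises(ValueError):
            validate_tradeoff(degenerate, toy_model)

    def test_perturbed_relation_fails(self, toy_model, toy_tradeoffs):
        t = next(t for t in toy_tradeoffs
                 if t.variable_support == {"R6", "R8"})
        bad_b = t.b.copy()
        bad_b[toy_model.reaction_index("R8")] *= -1  # flip one sign
        bad = TradeOff(b=bad_b, k=t.k, variable_support=t.variable_support,
                       fixed_support=t.fixed_support,
                       constant_T=t.constant_T, fixed_index=t.fixed_index)
        report = validate_tradeoff(bad, toy_model, n_samples=20, seed=3)
        assert not report.ok and report.violations


class TestNormalize:
    def test_rescaling_recovers_canonical_form(self, toy_model,
                                               toy_tradeoffs):
        t = next(t for t in toy_tradeoffs
                 if t.variable_support == {"R6", "R8"})
        doubled = TradeOff(b=2 * t.b, k=2 * t.k,
                           variable_support=t.variable_support,
                           fixed_support=t.fixed_support,
                           constant_T=2 * t.constant_T,
                           fixed_index=t.fixed_index)
        norm = normalize_tradeoff(doubled)
        assert np.allclose(norm.b, t.b)
        assert norm.constant_T == pytest.approx(t.constant_T)

    def test_already_normalized_is_unchanged(self, toy_tradeoffs):
        t = toy_tradeoffs.tradeoffs[0]
        norm = normalize_tradeoff(t)
        assert np.allclose(norm.b, t.b) and np.allclose(norm.k, t.k)

    def test_non_positive_fixed_sum_rejected(self, toy_tradeoffs):
        t = toy_tradeoffs.tradeoffs[0]
        flipped = TradeOff(b=-t.b, k=-t.k,
                           variable_support=t.variable_support,
                           fixed_support=t.fixed_support,
                           constant_T=-t.constant_T,
                           fixed_index=t.fixed_index)
        with pytest.raises(ValueError):
            normalize_tradeoff(flipped)


def test_json_round_trip(toy_model, toy_tradeoffs, tmp_path):
    path = tmp_path / "tradeoffs.json"
    tradeoffs_to_json(toy_tradeoffs, toy_model, path)
    again = tradeoffs_from_json(path, toy_model)
    assert again.termination_reason == toy_tradeoffs.termination_reason
    assert again.supports() == toy_tradeoffs.supports()
    for a, b in zip(again, toy_tradeoffs):
        assert np.allclose(a.b, b.b, atol=1e-12)
        assert a.constant_T == pytest.approx(b.constant_T)
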
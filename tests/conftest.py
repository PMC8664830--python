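import numpy as np
import pytest

import fluto


@pytest.fixture(scope="session")
def toy_model():
    return fluto.toy_network()


@pytest.fixture(scope="session")
def toy_classification(toy_model):
    _, classification = fluto.classify_model(toy_model)
    return classification


@pytest.fixture(scope="session")
def toy_tradeoffs(toy_model, toy_classification):
    return fluto.enumerate_tradeoffs(toy_model, toy_classification)


def to_cobra(model):
    """Convert a MetabolicModel to a COBRApy model (independent oracle)."""
    import cobra

    cm = cobra.Model("oracle")
    mets = {mid: cobra.Metabolite(mid, compartment="c")
            for mid in model.metabolite_ids}
    rxns = []
    for j, rid in enumerate(model.reaction_ids):
        rxn = cobra.Reaction(rid,
                             lower_bound=float(model.lower_bounds[j]),
                             upper_bound=float(model.upper_bounds[j]))
        rxns.append(rxn)
    cm.add_reactions(rxns)
    for j, rid in enumerate(model.reaction_ids):
        coeffs = {mets[model.metabolite_ids[i]]: float(model.S[i, j])
                  for i in np.nonzero(model.S[:, j])[0]}
        cm.reactions.get_by_id(rid).add_metabolites(coeffs)
    return cm


def supports_of(tradeoffs):
    return sorted(sorted(t.variable_support) for t in tradeoffs)
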
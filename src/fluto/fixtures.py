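"""Ground truth: the paradigmatic toy network, a brute-force trade-off
oracle for small networks, and a random-network generator with planted
trade-offs.

The oracle enumerates *every* candidate variable support by exhaustive subset
LP feasibility, so it performs the support minimization exactly (at a cost
that is only affordable on small networks).  It is deliberately independent
of the MILP path in :mod:`fluto.tradeoffs` — both sides share only the
problem definition, not the search strategy — which makes equality of the two
result sets a meaningful check.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .classify import classify_model, FIXED, FIXED_SIGN_VARIABLE
from .model import MetabolicModel
from .tradeoffs import (DEFAULT_BIG_M, DEFAULT_EPS_ACT, SolverConfig, TradeOff,
                        _System)


def toy_network() -> MetabolicModel:
    """The 8-metabolite / 12-reaction paradigmatic network.

    Reactions R3 and R5-R8 are internal, the rest are exchanges.  All bounds
    are [0, 10] (arbitrary units) except R5, which is fixed to 5.  The
    constrained network carries exactly ten absolute trade-offs, each pairing
    two variable reactions with the fixed R5; among them
    ``v5 - v6 - 2 v8 = 0``.

    Structure (M1..M8 are the metabolites)::

        R1:  -> M7          R7:  M3 -> M4 + M6
        R2:  M8 ->          R8:  2 M2 -> M3 + M5
        R3:  M7 -> 2 M8     R9:  M1 ->
        R4:  M8 ->          R10: M4 ->
        R5:  M1 -> M2       R11: M6 ->
        R6:  M2 -> 2 M1     R12: M5 ->
    """
    mets = [f"M{i}" for i in range(1, 9)]
    reactions = {
        "R1": {"M7": 1},
        "R2": {"M8": -1},
        "R3": {"M7": -1, "M8": 2},
        "R4": {"M8": -1},
        "R5": {"M1": -1, "M2": 1},
        "R6": {"M2": -1, "M1": 2},
        "R7": {"M3": -1, "M4": 1, "M6": 1},
        "R8": {"M2": -2, "M3": 1, "M5": 1},
        "R9": {"M1": -1},
        "R10": {"M4": -1},
        "R11": {"M6": -1},
        "R12": {"M5": -1},
    }
    rxn_ids = list(reactions)
    S = np.zeros((8, 12))
    for j, rid in enumerate(rxn_ids):
        for met, coeff in reactions[rid].items():
            S[mets.index(met), j] = coeff
    lb = np.zeros(12)
    ub = np.full(12, 10.0)
    j5 = rxn_ids.index("R5")
    lb[j5] = ub[j5] = 5.0
    return MetabolicModel(mets, rxn_ids, S, lb, ub)


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_tradeoffs(model: MetabolicModel,
                          classification,
                          max_support_size: int = 4,
                          eps_act: float = DEFAULT_EPS_ACT,
                          big_m: float = DEFAULT_BIG_M,
                          config: SolverConfig | None = None,
                          ) -> list[TradeOff]:
    """Exhaustive enumeration of inclusion-minimal trade-off supports.

    Every subset of fixed-sign variable reactions up to ``max_support_size``
    is tested by LP feasibility; minimal feasible supports are returned with
    one minimum-L1 witness each.  Guard: the number of subsets must not
    exceed 1e6.
    """
    sys_ = _System(model, classification)
    n = sys_.nv
    total = sum(math.comb(n, s) for s in range(1, max_support_size + 1))
    if total > 1_000_000:
        raise ValueError(
            f"{total} candidate subsets exceed the enumeration guard; "
            "use a smaller max_support_size")
    if sys_.nf == 0:
        return []
    found: list[TradeOff] = []
    minimal: list[set[int]] = []
    for size in range(1, max_support_size + 1):
        for sub in itertools.combinations(range(n), size):
            if any(m <= set(sub) for m in minimal):
                continue  # superset of a known minimal support
            lp = sys_.subset_feasible(sub, eps_act, big_m, config)
            if lp is None:
                continue
            minimal.append(set(sub))
            found.append(sys_.extract(lp.x, sub, objective=lp.fun))
    return found


# ---------------------------------------------------------------------------
# planted-network generator
# ---------------------------------------------------------------------------

@dataclass
class GeneratorParams:
    """Knobs of the planted-network generator.

    Defaults generate a small network in the regime used for benchmarking:
    about a dozen reactions, one fixed uptake anchoring one planted
    trade-off, and a random irreversible background.
    """
    n_metabolites: int = 10
    n_reactions: int = 14
    n_fixed: int = 1
    n_planted: int = 1
    seed: int | None = None


@dataclass
class PlantedTradeOff:
    """Ground-truth planted relation ``c_f v_fixed = sum_j c_j v_j``."""
    fixed_reaction: str
    variable_support: frozenset[str]
    b: dict[str, float]


@dataclass
class PlantedNetwork:
    model: MetabolicModel
    planted_tradeoffs: list[PlantedTradeOff]
    generator_params: GeneratorParams = field(default_factory=GeneratorParams)


def generate_planted_network(params: GeneratorParams,
                             seed: int | None = None) -> PlantedNetwork:
    """Construct a random feasible irreversible network with planted
    absolute trade-offs.

    Each planted trade-off is realized as a pool metabolite fed by a
    bound-fixed uptake (integer stoichiometry in {1, 2, 3}) and drained by
    2-4 variable consumer reactions; consumers are either direct exports or
    internal conversions followed by an export.  Extra fixed reactions feed
    pass-through chains, and the remaining reaction budget is filled with a
    random irreversible background on disjoint metabolites (guaranteeing
    feasibility and leaving the planted relations intact).  The requested
    dimensions are upper bounds: a network may come out slightly smaller
    when the random structure exhausts the metabolite budget first.
    Reproducible from ``(params, seed)``.
    """
    if params.n_planted < 1:
        raise ValueError("n_planted must be >= 1")
    if params.n_fixed < 1:
        raise ValueError("n_fixed must be >= 1")
    if params.n_fixed < params.n_planted:
        raise ValueError("need at least one fixed reaction per planted "
                         "trade-off")
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)

    mets: list[str] = []
    rxns: list[tuple[str, dict[str, float], float, float]] = []  # id, stoich, lb, ub
    planted: list[PlantedTradeOff] = []

    def add_rxn(rid, stoich, lb=0.0, ub=10.0):
        rxns.append((rid, stoich, lb, ub))

    drainable: list[str] = []  # metabolites that tolerate an extra export

    for p in range(params.n_planted):
        # budget reserved for remaining planted trade-offs (importer + two
        # direct consumers each) and for the extra fixed chains
        reserve_rxns = 3 * (params.n_planted - p - 1) \
            + 2 * (params.n_fixed - params.n_planted)
        reserve_mets = (params.n_planted - p - 1) \
            + (params.n_fixed - params.n_planted)
        avail_rxns = params.n_reactions - len(rxns) - reserve_rxns
        avail_mets = params.n_metabolites - len(mets) - reserve_mets
        if avail_rxns < 3 or avail_mets < 1:
            raise ValueError(
                f"requested dimensions ({params.n_metabolites} metabolites, "
                f"{params.n_reactions} reactions) are too small for "
                f"{params.n_planted} planted trade-offs and "
                f"{params.n_fixed} fixed reactions")
        pool = f"P{p}"
        mets.append(pool)
        avail_mets -= 1
        c_f = int(rng.integers(1, 4))
        value = float(rng.integers(2, 7))
        fid = f"FIX{p}"
        add_rxn(fid, {pool: c_f}, value, value)
        avail_rxns -= 1
        n_cons = min(int(rng.integers(2, 5)), avail_rxns)
        b = {fid: float(c_f)}
        support = []
        for c in range(n_cons):
            coeff = int(rng.integers(1, 4))
            cid = f"C{p}_{c}"
            support.append(cid)
            b[cid] = -float(coeff)
            budget_left = avail_rxns - (n_cons - c)  # slots for later ones
            if rng.random() < 0.4 and budget_left >= 1 and avail_mets >= 1:
                # internal consumer with its own product and export
                prod = f"Q{p}_{c}"
                mets.append(prod)
                avail_mets -= 1
                add_rxn(cid, {pool: -coeff, prod: 1})
                add_rxn(f"E{p}_{c}", {prod: -1})
                avail_rxns -= 2
            else:
                add_rxn(cid, {pool: -coeff})
                avail_rxns -= 1
        planted.append(PlantedTradeOff(fid, frozenset(support),
                                       {k: v / c_f for k, v in b.items()}))

    for f in range(params.n_planted, params.n_fixed):
        chain = f"Z{f}"
        mets.append(chain)
        value = float(rng.integers(2, 7))
        add_rxn(f"FIX{f}", {chain: 1}, value, value)
        add_rxn(f"ZOUT{f}", {chain: -1})
        drainable.append(chain)

    # random irreversible background on disjoint metabolites
    bg_mets: list[str] = []
    while len(rxns) + 2 <= params.n_reactions and \
            len(mets) + 1 <= params.n_metabolites:
        mid = f"B{len(bg_mets)}"
        bg_mets.append(mid)
        mets.append(mid)
        add_rxn(f"IN_{mid}", {mid: 1})
        add_rxn(f"OUT_{mid}", {mid: -1})
    extra = 0
    while len(rxns) < params.n_reactions:
        if len(bg_mets) >= 2:
            a, b_ = rng.choice(len(bg_mets), size=2, replace=False)
            stoich = {bg_mets[a]: -float(rng.integers(1, 4)),
                      bg_mets[b_]: float(rng.integers(1, 4))}
        elif bg_mets:
            stoich = {bg_mets[0]: -1.0}
        elif drainable:
            # extra export on a pass-through chain metabolite: adds a valid
            # alternative route without touching any planted pool relation
            stoich = {drainable[extra % len(drainable)]: -1.0}
        else:
            break  # metabolite budget exhausted; stop below the target
        add_rxn(f"BG{extra}", stoich)
        extra += 1
    while len(mets) < params.n_metabolites:
        mets.append(f"PAD{len(mets)}")  # isolated row; trivially balanced
    if len(rxns) > params.n_reactions or len(mets) > params.n_metabolites:
        raise ValueError(
            f"requested dimensions ({params.n_metabolites} metabolites, "
            f"{params.n_reactions} reactions) are too small for "
            f"{params.n_planted} planted trade-offs; got {len(mets)} "
            f"metabolites / {len(rxns)} reactions")

    S = np.zeros((len(mets), len(rxns)))
    rxn_ids = []
    lbs, ubs = [], []
    for j, (rid, stoich, lb, ub) in enumerate(rxns):
        rxn_ids.append(rid)
        lbs.append(lb)
        ubs.append(ub)
        for met, coeff in stoich.items():
            S[mets.index(met), j] = coeff
    model = MetabolicModel(mets, rxn_ids, S, np.array(lbs), np.array(ubs))
    _check_planted(model, planted)
    return PlantedNetwork(model, planted,
                          GeneratorParams(params.n_metabolites,
                                          params.n_reactions, params.n_fixed,
                                          params.n_planted, seed))


def _check_planted(model: MetabolicModel,
                   planted: list[PlantedTradeOff]) -> None:
    """Verify the planted relations hold in the generated model: each fixed
    anchor classifies as fixed, each support member as fixed-sign variable,
    and the planted b lies in the row space of S."""
    _, classification = classify_model(model)
    for p in planted:
        if classification.category_of(p.fixed_reaction) != FIXED:
            raise RuntimeError(
                f"planted anchor {p.fixed_reaction} is not fixed")
        for rid in p.variable_support:
            if classification.category_of(rid) != FIXED_SIGN_VARIABLE:
                raise RuntimeError(
                    f"planted support member {rid} is not fixed-sign variable")
        b = np.zeros(model.n_reactions)
        for rid, coeff in p.b.items():
            b[model.reaction_index(rid)] = coeff
        k, *_ = np.linalg.lstsq(model.S.T, b, rcond=None)
        if np.max(np.abs(model.S.T @ k - b)) > 1e-8:
            raise RuntimeError("planted b is not in the row space of S")
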
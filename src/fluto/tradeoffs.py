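"""Step 2: enumeration of absolute flux trade-offs.

An absolute trade-off is a non-negative linear combination of variable
reaction fluxes that is forced to a constant by the network's mass balance
and its fixed reactions.  Formally we look for a row combination
``b = k S`` (``k`` over real metabolite rows) such that

* ``b_i <= 0`` for every fixed-sign variable reaction (so ``-b_i >= 0`` are
  the non-negative weights of the combination),
* ``b_i = 0`` for blocked and sign-variable reactions,
* ``sum(b_i) >= 1`` over the fixed reactions (anchoring the constant).

For any feasible flux ``v``, ``b . v = 0``, hence
``sum_variable (-b_i) v_i = sum_fixed b_i v_i = T``: a resource pool of
constant size ``T`` shared by the variable reactions.  Support minimization is
NP-hard and is approximated by minimizing ``||b||_1`` (cast as an LP through a
``b = b+ - b-`` split), with binary support indicators attached through a
big-M linking so previously found supports can be excluded by integer cuts.
The cut ``sum_{i in S} y_i <= |S| - 1`` forbids a found support *and all its
supersets*, which makes the enumerated variable supports an antichain of
minimal trade-offs and guarantees termination.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from ._lp import INFEASIBLE, OPTIMAL, SolverError, check_solver, solve_lp, solve_milp
from .classify import (FIXED, FIXED_SIGN_VARIABLE, InfeasibleModelError,
                       ReactionClassification)
from .model import MetabolicModel

logger = logging.getLogger(__name__)

#: activation threshold for a support member on the normalized scale
DEFAULT_EPS_ACT = 1e-3
#: big-M linking coefficient; M/eps conditioning stays at 1e6
DEFAULT_BIG_M = 1e3
#: entries below this magnitude are snapped to zero
EPS_ZERO = 1e-9


@dataclass
class SolverConfig:
    solver: str = "highs"
    time_limit_s: float | None = None
    mip_gap: float | None = None
    seed: int = 0


@dataclass
class TradeOff:
    """One enumerated trade-off.

    ``b`` is the per-reaction coefficient vector of the row combination
    (normalized so the fixed-reaction coefficients sum to 1), ``k`` the
    witness combination weights per metabolite (zero on auxiliary rows), and
    ``constant_T`` the size of the shared resource pool:
    ``sum_variable (-b_i) v_i = T`` for every feasible ``v``.
    """

    b: np.ndarray
    k: np.ndarray
    variable_support: frozenset[str]
    fixed_support: frozenset[str]
    constant_T: float
    objective: float = float("nan")
    iteration: int = -1
    solver_status: str = OPTIMAL
    #: positions in ``b`` of the fixed-support coefficients
    fixed_index: tuple[int, ...] = ()

    @property
    def size(self) -> int:
        """Number of participating variable reactions (fixed not counted)."""
        return len(self.variable_support)

    def coefficient(self, model: MetabolicModel, rid: str) -> float:
        return float(self.b[model.reaction_index(rid)])


@dataclass
class TradeOffSet:
    """Ordered enumeration result with provenance."""

    tradeoffs: list[TradeOff] = field(default_factory=list)
    termination_reason: str = "infeasible"

    def __len__(self) -> int:
        return len(self.tradeoffs)

    def __iter__(self):
        return iter(self.tradeoffs)

    def supports(self) -> list[frozenset[str]]:
        return [t.variable_support for t in self.tradeoffs]

    def size_histogram(self) -> dict[int, int]:
        hist: dict[int, int] = {}
        for t in self.tradeoffs:
            hist[t.size] = hist.get(t.size, 0) + 1
        return dict(sorted(hist.items()))


@dataclass
class ValidationReport:
    ok: bool
    violations: list[str]
    constant_values: np.ndarray

    def __bool__(self) -> bool:
        return self.ok


# ---------------------------------------------------------------------------
# shared constraint-system builder
# ---------------------------------------------------------------------------

class _System:
    """Index bookkeeping and constraint blocks shared by the MILP and the
    subset-feasibility LPs."""

    def __init__(self, model: MetabolicModel,
                 classification: ReactionClassification):
        self.model = model
        structural = model.structural_reaction_mask
        self.rows = np.nonzero(model.structural_row_mask)[0]
        self.S_real = model.S[self.rows, :]
        cat = {rid: c for rid, c in zip(classification.reaction_ids,
                                        classification.category)}
        self.fixed_idx = [j for j, rid in enumerate(model.reaction_ids)
                          if structural[j] and cat.get(rid) == FIXED]
        self.fsvar_idx = [j for j, rid in enumerate(model.reaction_ids)
                          if structural[j]
                          and cat.get(rid) == FIXED_SIGN_VARIABLE]
        self.fixed_value = classification.fixed_value
        self.nk = len(self.rows)
        self.nf = len(self.fixed_idx)
        self.nv = len(self.fsvar_idx)

    # variable layout (LP): [k (nk), bp (nf), bm (nf), u (nv)]
    def lp_blocks(self):
        nk, nf, nv = self.nk, self.nf, self.nv
        n = nk + 2 * nf + nv
        r = self.model.n_reactions
        A = sp.lil_matrix((r + 1, n))
        A[:r, :nk] = self.S_real.T
        for p, j in enumerate(self.fixed_idx):
            A[j, nk + p] = -1.0
            A[j, nk + nf + p] = 1.0
            A[r, nk + p] = 1.0
            A[r, nk + nf + p] = -1.0
        for q, j in enumerate(self.fsvar_idx):
            A[j, nk + 2 * nf + q] = 1.0
        lb = np.zeros(r + 1)
        ub = np.zeros(r + 1)
        lb[r], ub[r] = 1.0, np.inf  # sum_fixed b >= 1
        return A, lb, ub, n

    def subset_feasible(self, support: tuple[int, ...],
                        eps_act: float, big_m: float,
                        config: SolverConfig | None = None):
        """Minimum-L1 witness with the variable support pinned to ``support``
        (indices into ``fsvar_idx``); ``None`` if infeasible."""
        A, lb, ub, n = self.lp_blocks()
        nk, nf, nv = self.nk, self.nf, self.nv
        bounds: list[tuple[float | None, float | None]] = \
            [(None, None)] * nk + [(0.0, None)] * (2 * nf)
        in_support = set(support)
        for q in range(nv):
            bounds.append((eps_act, big_m) if q in in_support else (0.0, 0.0))
        c = np.concatenate([np.zeros(nk), np.ones(2 * nf + nv)])
        res = solve_lp(c, A_eq=A.tocsr()[:-1], b_eq=np.zeros(A.shape[0] - 1),
                       A_ub=-A.tocsr()[-1:], b_ub=[-1.0], bounds=bounds,
                       time_limit_s=config.time_limit_s if config else None)
        if not res.optimal:
            return None
        return res

    def extract(self, x: np.ndarray, support: tuple[int, ...],
                objective: float, iteration: int = -1) -> TradeOff:
        """Build a normalized :class:`TradeOff` from an LP solution vector."""
        model = self.model
        nk, nf = self.nk, self.nf
        b = np.zeros(model.n_reactions)
        for p, j in enumerate(self.fixed_idx):
            b[j] = x[nk + p] - x[nk + nf + p]
        for q in support:
            b[self.fsvar_idx[q]] = -x[nk + 2 * nf + q]
        k = np.zeros(model.n_metabolites)
        k[self.rows] = x[:nk]
        scale = sum(b[j] for j in self.fixed_idx)
        if scale <= 0:
            raise SolverError(
                "fixed-reaction coefficients sum to a non-positive value; "
                "solver tolerance issue")
        b /= scale
        k /= scale
        b[np.abs(b) < EPS_ZERO] = 0.0
        variable_support = frozenset(model.reaction_ids[self.fsvar_idx[q]]
                                     for q in support)
        fixed_support = frozenset(model.reaction_ids[j]
                                  for j in self.fixed_idx
                                  if abs(b[j]) > EPS_ZERO)
        constant_T = float(sum(
            b[model.reaction_index(rid)] * self.fixed_value[rid]
            for rid in fixed_support))
        return TradeOff(b=b, k=k, variable_support=variable_support,
                        fixed_support=fixed_support, constant_T=constant_T,
                        objective=objective, iteration=iteration,
                        fixed_index=tuple(j for j in self.fixed_idx
                                          if abs(b[j]) > EPS_ZERO))


# ---------------------------------------------------------------------------
# single trade-off MILP
# ---------------------------------------------------------------------------

def find_tradeoff(model: MetabolicModel,
                  classification: ReactionClassification,
                  excluded_supports: list[frozenset[str]] = (),
                  eps_act: float = DEFAULT_EPS_ACT,
                  big_m: float = DEFAULT_BIG_M,
                  max_reduction_size: int = 6,
                  config: SolverConfig | None = None,
                  iteration: int = -1) -> TradeOff | None:
    """Solve the L1-minimizing MILP for one trade-off, excluding the given
    variable supports and all their supersets.

    Returns ``None`` when no trade-off remains (or when the classification
    contains no fixed reaction, in which case no trade-off can exist).
    After the MILP solve, a support-reduction pass re-solves the restricted
    LP on proper subsets (smallest first, up to ``max_reduction_size``) and
    keeps the smallest feasible support, since L1 minimization only
    approximates support minimization.
    """
    if config is not None:
        check_solver(config.solver)
    sys_ = _System(model, classification)
    if sys_.nf == 0:
        logger.info("no fixed reactions: no trade-offs exist "
                    "(reason=no_fixed_reactions)")
        return None
    if sys_.nv == 0:
        return None

    A, lb, ub, n_lp = sys_.lp_blocks()
    nk, nf, nv = sys_.nk, sys_.nf, sys_.nv
    rid_to_q = {model.reaction_ids[j]: q
                for q, j in enumerate(sys_.fsvar_idx)}
    n = n_lp + nv  # append binaries y
    rows = [sp.hstack([A.tocsr(), sp.csr_matrix((A.shape[0], nv))])]
    lbs = [lb]
    ubs = [ub]
    u0 = nk + 2 * nf
    # eps*y <= u <= M*y
    link = sp.lil_matrix((2 * nv, n))
    link_lb = np.empty(2 * nv)
    link_ub = np.empty(2 * nv)
    for q in range(nv):
        link[q, u0 + q] = 1.0
        link[q, n_lp + q] = -big_m
        link_lb[q], link_ub[q] = -np.inf, 0.0
        link[nv + q, u0 + q] = 1.0
        link[nv + q, n_lp + q] = -eps_act
        link_lb[nv + q], link_ub[nv + q] = 0.0, np.inf
    rows.append(link.tocsr())
    lbs.append(link_lb)
    ubs.append(link_ub)
    # at least one variable reaction participates
    ones_y = sp.csr_matrix((np.ones(nv), (np.zeros(nv, dtype=int),
                                          np.arange(n_lp, n))), shape=(1, n))
    rows.append(ones_y)
    lbs.append(np.array([1.0]))
    ubs.append(np.array([np.inf]))
    # integer cuts: forbid each excluded support and its supersets
    for sup in excluded_supports:
        qs = [rid_to_q[rid] for rid in sup if rid in rid_to_q]
        if len(qs) != len(sup):
            continue  # support references reactions outside this system
        cut = sp.csr_matrix((np.ones(len(qs)),
                             (np.zeros(len(qs), dtype=int),
                              [n_lp + q for q in qs])), shape=(1, n))
        rows.append(cut)
        lbs.append(np.array([-np.inf]))
        ubs.append(np.array([float(len(qs) - 1)]))

    c = np.concatenate([np.zeros(nk), np.ones(2 * nf + nv), np.zeros(nv)])
    integrality = np.concatenate([np.zeros(n_lp), np.ones(nv)])
    var_lb = np.concatenate([np.full(nk, -np.inf), np.zeros(2 * nf),
                             np.zeros(nv), np.zeros(nv)])
    var_ub = np.concatenate([np.full(nk, np.inf), np.full(2 * nf, np.inf),
                             np.full(nv, big_m), np.ones(nv)])
    res = solve_milp(c, sp.vstack(rows).tocsc(), np.concatenate(lbs),
                     np.concatenate(ubs), integrality, var_lb, var_ub,
                     time_limit_s=config.time_limit_s if config else None,
                     mip_gap=config.mip_gap if config else None)
    if res.status == INFEASIBLE:
        return None
    if not res.optimal:
        raise SolverError(f"trade-off MILP ended with status {res.status}",
                          status=res.status)

    u = res.x[u0:u0 + nv]
    support = tuple(q for q in range(nv) if u[q] >= eps_act / 2)
    if not support:
        raise SolverError("MILP returned an empty variable support")
    support = _reduce_support(sys_, support, eps_act, big_m,
                              max_reduction_size, config)
    # canonical witness: min-L1 LP restricted to the final support
    lp = sys_.subset_feasible(support, eps_act, big_m, config)
    if lp is None:
        raise SolverError("restricted LP infeasible for the MILP support; "
                          "solver tolerance issue")
    return sys_.extract(lp.x, support, objective=lp.fun, iteration=iteration)


def _reduce_support(sys_: _System, support: tuple[int, ...], eps_act: float,
                    big_m: float, max_reduction_size: int,
                    config: SolverConfig | None) -> tuple[int, ...]:
    for size in range(1, len(support)):
        if size > max_reduction_size:
            break
        for sub in itertools.combinations(support, size):
            if sys_.subset_feasible(sub, eps_act, big_m, config) is not None:
                return sub
    return support


# ---------------------------------------------------------------------------
# enumeration with integer cuts
# ---------------------------------------------------------------------------

def enumerate_tradeoffs(model: MetabolicModel,
                        classification: ReactionClassification,
                        max_iterations: int = 200,
                        max_size: int | None = None,
                        eps_act: float = DEFAULT_EPS_ACT,
                        big_m: float = DEFAULT_BIG_M,
                        config: SolverConfig | None = None,
                        validation_samples: int = 8) -> TradeOffSet:
    """Enumerate all minimal absolute trade-offs by repeated MILP solves with
    integer cuts.

    Each found variable support is added to the exclusion list (forbidding it
    and all supersets), so the result is an antichain of minimal supports.
    Each trade-off is validated (:func:`validate_tradeoff` with
    ``validation_samples`` sampled flux distributions) before inclusion.
    Termination reason is ``infeasible`` (enumeration exhausted),
    ``iteration_cap``, or ``objective_cap`` (a trade-off exceeded
    ``max_size``).
    """
    result = TradeOffSet([], "infeasible")
    excluded: list[frozenset[str]] = []
    for i in range(max_iterations):
        try:
            to = find_tradeoff(model, classification, excluded,
                               eps_act=eps_act, big_m=big_m, config=config,
                               iteration=i)
        except SolverError as exc:
            raise SolverError(f"iteration {i}: {exc}",
                              status=exc.status) from exc
        if to is None:
            result.termination_reason = "infeasible"
            return result
        if max_size is not None and to.size > max_size:
            result.termination_reason = "objective_cap"
            return result
        if validation_samples > 0:
            report = validate_tradeoff(
                to, model, n_samples=validation_samples,
                seed=config.seed if config else 0)
            if not report.ok:
                raise SolverError(
                    f"iteration {i}: enumerated trade-off failed validation: "
                    f"{report.violations}")
        logger.info("iteration %d: objective=%.6g support=%s", i,
                    to.objective, sorted(to.variable_support))
        result.tradeoffs.append(to)
        excluded.append(to.variable_support)
    result.termination_reason = "iteration_cap"
    return result


# ---------------------------------------------------------------------------
# validation and normalization
# ---------------------------------------------------------------------------

def validate_tradeoff(tradeoff: TradeOff, model: MetabolicModel,
                      n_samples: int = 100, seed: int = 0) -> ValidationReport:
    """Check a trade-off against the model.

    (a) ``b`` lies in the row space of the real rows of ``S`` (least-squares
    residual), (b) ``b . v = 0`` on ``n_samples`` feasible flux distributions
    obtained by optimizing random seeded objectives, and (c) the weighted sum
    of variable fluxes equals ``constant_T`` on every sample.
    """
    b = tradeoff.b
    if not np.any(np.abs(b) > EPS_ZERO):
        raise ValueError("degenerate trade-off: b is the zero vector")
    violations: list[str] = []
    S_real = model.S[model.structural_row_mask, :]
    k_fit, *_ = np.linalg.lstsq(S_real.T, b, rcond=None)
    residual = np.max(np.abs(S_real.T @ k_fit - b))
    if residual > 1e-6 * np.max(np.abs(b)):
        violations.append(f"row-space residual {residual:.3g}")

    rng = np.random.default_rng(seed)
    r = model.n_reactions
    bounds = list(zip(
        (None if np.isneginf(l) else l for l in model.lower_bounds),
        (None if np.isposinf(u) else u for u in model.upper_bounds)))
    beq = np.zeros(model.n_metabolites)
    var_idx = [model.reaction_index(rid)
               for rid in sorted(tradeoff.variable_support)]
    norm_b1 = np.sum(np.abs(b))
    constants = []
    sampled = 0
    attempts = 0
    while sampled < n_samples and attempts < 5 * n_samples:
        attempts += 1
        c = rng.standard_normal(r)
        res = solve_lp(-c, A_eq=model.S, b_eq=beq, bounds=bounds)
        if res.status == INFEASIBLE:
            raise InfeasibleModelError("model is infeasible")
        if not res.optimal:
            continue  # unbounded direction; redraw
        v = res.x
        tol = 1e-6 * norm_b1 * max(np.max(np.abs(v)), 1e-3)
        if abs(b @ v) > tol:
            violations.append(
                f"sample {sampled}: |b.v| = {abs(b @ v):.3g} > {tol:.3g}")
        pool = -sum(b[j] * v[j] for j in var_idx)
        constants.append(pool)
        if abs(pool - tradeoff.constant_T) > tol:
            violations.append(
                f"sample {sampled}: pool {pool:.6g} != T "
                f"{tradeoff.constant_T:.6g}")
        sampled += 1
    if sampled < n_samples:
        violations.append(
            f"only {sampled}/{n_samples} feasible samples obtained")
    return ValidationReport(not violations, violations, np.array(constants))


def normalize_tradeoff(tradeoff: TradeOff,
                       eps_zero: float = EPS_ZERO) -> TradeOff:
    """Rescale ``b`` and ``k`` by a positive scalar so the fixed-support
    coefficients sum to 1 (trade-off relations are scale-invariant; this is
    the canonical form).  Near-zero entries are snapped to exactly 0."""
    if not tradeoff.fixed_index:
        raise ValueError("trade-off has no recorded fixed-support positions")
    scale = float(sum(tradeoff.b[j] for j in tradeoff.fixed_index))
    if scale <= 0:
        raise ValueError(
            "fixed-support coefficients sum to a non-positive value "
            f"({scale:.3g}); solver tolerance issue")
    b = tradeoff.b / scale
    k = tradeoff.k / scale
    b[np.abs(b) < eps_zero] = 0.0
    k[np.abs(k) < eps_zero] = 0.0
    return TradeOff(b=b, k=k, variable_support=tradeoff.variable_support,
                    fixed_support=tradeoff.fixed_support,
                    constant_T=tradeoff.constant_T / scale,
                    objective=tradeoff.objective,
                    iteration=tradeoff.iteration,
                    solver_status=tradeoff.solver_status,
                    fixed_index=tradeoff.fixed_index)


def tradeoffs_to_tsv(tradeoffs: TradeOffSet, model: MetabolicModel,
                     path: str | Path) -> None:
    """One row per participating reaction: id, coefficient, role, subsystems."""
    lines = ["trade_off_id\treaction_id\tcoefficient\trole\tsubsystems"]
    for t_id, t in enumerate(tradeoffs):
        for rid in sorted(t.fixed_support) + sorted(t.variable_support):
            j = model.reaction_index(rid)
            role = "fixed" if rid in t.fixed_support else "variable"
            subs = ";".join(model.subsystems[j])
            lines.append(f"{t_id}\t{rid}\t{t.b[j]!r}\t{role}\t{subs}")
    Path(path).write_text("\n".join(lines) + "\n")


def tradeoffs_to_json(tradeoffs: TradeOffSet, model: MetabolicModel,
                      path: str | Path | None = None) -> dict:
    data = {
        "termination_reason": tradeoffs.termination_reason,
        "tradeoffs": [
            {
                "iteration": t.iteration,
                "objective": t.objective,
                "solver_status": t.solver_status,
                "constant_T": t.constant_T,
                "variable_support": sorted(t.variable_support),
                "fixed_support": sorted(t.fixed_support),
                "b": {rid: float(t.b[j])
                      for j, rid in enumerate(model.reaction_ids)
                      if abs(t.b[j]) > EPS_ZERO},
                "k": {mid: float(t.k[i])
                      for i, mid in enumerate(model.metabolite_ids)
                      if abs(t.k[i]) > EPS_ZERO},
            }
            for t in tradeoffs
        ],
    }
    if path is not None:
        Path(path).write_text(json.dumps(data, indent=1))
    return data


def tradeoffs_from_json(data: dict | str | Path,
                        model: MetabolicModel) -> TradeOffSet:
    if not isinstance(data, dict):
        data = json.loads(Path(data).read_text())
    out = TradeOffSet([], data["termination_reason"])
    for entry in data["tradeoffs"]:
        b = np.zeros(model.n_reactions)
        for rid, val in entry["b"].items():
            b[model.reaction_index(rid)] = val
        k = np.zeros(model.n_metabolites)
        for mid, val in entry["k"].items():
            k[model.metabolite_index(mid)] = val
        out.tradeoffs.append(TradeOff(
            b=b, k=k,
            variable_support=frozenset(entry["variable_support"]),
            fixed_support=frozenset(entry["fixed_support"]),
            constant_T=entry["constant_T"], objective=entry["objective"],
            iteration=entry["iteration"],
            solver_status=entry["solver_status"],
            fixed_index=tuple(model.reaction_index(rid)
                              for rid in sorted(entry["fixed_support"]))))
    return out
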
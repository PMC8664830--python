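"""Thin wrappers around scipy's HiGHS interface for LPs and MILPs.

All optimization in this package funnels through these two functions so that
solver options, status handling, and determinism live in one place.  HiGHS is
deterministic for a fixed problem, which makes enumeration orders reproducible
without an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

#: statuses shared by linprog and milp
OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"

_LINPROG_STATUS = {0: OPTIMAL, 2: INFEASIBLE, 3: UNBOUNDED}
_MILP_STATUS = {0: OPTIMAL, 2: INFEASIBLE, 3: UNBOUNDED}

SUPPORTED_SOLVERS = ("highs",)


class SolverError(RuntimeError):
    """Raised when the LP/MILP backend fails for a reason other than
    infeasibility (numerical failure, iteration/time limit, ...)."""

    def __init__(self, message: str, status: str = "error"):
        super().__init__(message)
        self.status = status


def check_solver(solver: str) -> None:
    if solver not in SUPPORTED_SOLVERS:
        raise SolverError(
            f"solver {solver!r} is not available in this build; "
            f"supported: {', '.join(SUPPORTED_SOLVERS)}"
        )


@dataclass
class LpResult:
    status: str
    x: np.ndarray | None
    fun: float | None

    @property
    def optimal(self) -> bool:
        return self.status == OPTIMAL


def solve_lp(
    c,
    A_eq=None,
    b_eq=None,
    A_ub=None,
    b_ub=None,
    bounds=None,
    time_limit_s: float | None = None,
) -> LpResult:
    """Solve ``min c.x  s.t.  A_eq x = b_eq, A_ub x <= b_ub, lb <= x <= ub``.

    ``bounds`` is a sequence of ``(lb, ub)`` pairs (``None`` for infinity).
    Infeasible and unbounded problems are reported via the status, every other
    failure raises :class:`SolverError`.
    """
    options = {}
    if time_limit_s is not None:
        options["time_limit"] = time_limit_s
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=bounds,
        method="highs",
        options=options,
    )
    status = _LINPROG_STATUS.get(res.status)
    if status is None:
        raise SolverError(f"LP failed: {res.message}", status=str(res.status))
    return LpResult(status, res.x if status == OPTIMAL else None,
                    res.fun if status == OPTIMAL else None)


def solve_milp(
    c,
    A: sp.spmatrix,
    lb_con,
    ub_con,
    integrality,
    var_lb,
    var_ub,
    time_limit_s: float | None = None,
    mip_gap: float | None = None,
) -> LpResult:
    """Solve a MILP with a single stacked linear-constraint block.

    ``lb_con <= A x <= ub_con`` with per-variable bounds and an integrality
    marker vector (0 continuous, 1 integer).
    """
    options = {}
    if time_limit_s is not None:
        options["time_limit"] = time_limit_s
    if mip_gap is not None:
        options["mip_rel_gap"] = mip_gap
    res = milp(
        c=c,
        constraints=LinearConstraint(A, lb_con, ub_con),
        integrality=integrality,
        bounds=Bounds(var_lb, var_ub),
        options=options,
    )
    status = _MILP_STATUS.get(res.status)
    if status is None:
        raise SolverError(f"MILP failed: {res.message}", status=str(res.status))
    return LpResult(status, res.x if status == OPTIMAL else None,
                    res.fun if status == OPTIMAL else None)
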
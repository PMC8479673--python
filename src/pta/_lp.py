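"""Thin wrapper around scipy's HiGHS interface for the LPs used throughout.

All linear programs in this package share the steady-state structure
``S v = 0, lb <= v <= ub`` plus optional extra inequality rows.  Centralising
them here keeps solver options (presolve, tolerances) consistent and makes
LP call counting possible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

__all__ = ["LPResult", "solve_lp", "steady_state_lp", "lp_call_count"]

_N_CALLS = 0


def lp_call_count() -> int:
    """Number of LPs solved since import (diagnostic only)."""
    return _N_CALLS


@dataclass
class LPResult:
    status: str  # "optimal" | "infeasible" | "unbounded" | "error"
    x: np.ndarray | None
    fun: float | None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def solve_lp(
    c: np.ndarray,
    A_eq: np.ndarray | None = None,
    b_eq: np.ndarray | None = None,
    A_ub: np.ndarray | None = None,
    b_ub: np.ndarray | None = None,
    bounds: list[tuple[float, float]] | None = None,
) -> LPResult:
    global _N_CALLS
    _N_CALLS += 1
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=bounds,
        method="highs",
    )
    status = _STATUS.get(res.status, "error")
    x = np.asarray(res.x) if res.x is not None else None
    return LPResult(status=status, x=x, fun=res.fun if res.success else None)


def steady_state_lp(
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    c: np.ndarray | None = None,
    extra_lb: dict[int, float] | None = None,
    extra_ub: dict[int, float] | None = None,
) -> LPResult:
    """Solve ``min c.v  s.t.  S v = 0,  lb' <= v <= ub'``.

    ``extra_lb``/``extra_ub`` tighten individual reaction bounds (used for
    direction constraints).  A ``None`` objective solves a pure feasibility
    problem.
    """
    n = S.shape[1]
    lo = np.array(lb, dtype=float)
    hi = np.array(ub, dtype=float)
    if extra_lb:
        for i, v in extra_lb.items():
            lo[i] = max(lo[i], v)
    if extra_ub:
        for i, v in extra_ub.items():
            hi[i] = min(hi[i], v)
    if np.any(lo > hi + 1e-12):
        return LPResult(status="infeasible", x=None, fun=None)
    obj = np.zeros(n) if c is None else np.asarray(c, dtype=float)
    return solve_lp(
        obj, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=list(zip(lo, hi))
    )
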
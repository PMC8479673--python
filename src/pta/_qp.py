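"""Minimum-norm point in a polyhedron ``{m : A m <= b}``.

This is the convex kernel of probabilistic metabolic optimization: within a
fixed assignment of reaction directions the sign constraints on the
reaction energies are linear in the reduced coordinates ``m``, and the most
probable point is the Euclidean projection of the origin onto the
polyhedron.  We solve the dual

    min_{lam >= 0}  1/4 lam^T A A^T lam + b^T lam,      m = -A^T lam / 2

with L-BFGS-B and then polish the result by solving the equality-
constrained least-norm problem on the active set, which recovers the
solution to near machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog, minimize

__all__ = ["QPResult", "min_norm_in_polyhedron"]


@dataclass
class QPResult:
    status: str  # "optimal" | "infeasible"
    m: np.ndarray | None
    objective: float | None  # ||m||^2


def _polyhedron_feasible(A: np.ndarray, b: np.ndarray) -> np.ndarray | None:
    """Return a feasible point or None (phase-1 LP)."""
    n = A.shape[1]
    res = linprog(
        np.zeros(n),
        A_ub=A,
        b_ub=b,
        bounds=[(None, None)] * n,
        method="highs",
    )
    return np.asarray(res.x) if res.status == 0 else None


def min_norm_in_polyhedron(
    A: np.ndarray | None, b: np.ndarray | None, tol: float = 1e-10
) -> QPResult:
    """Project the origin onto ``{m : A m <= b}``.

    Returns the squared norm of the projection; ``infeasible`` when the
    polyhedron is empty.  With no constraints the answer is the origin.
    """
    if A is None or len(A) == 0:
        n = 0 if A is None else A.shape[1]
        return QPResult("optimal", np.zeros(n), 0.0)
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    n = A.shape[1]
    if np.all(b >= 0.0):  # origin already feasible
        return QPResult("optimal", np.zeros(n), 0.0)
    if _polyhedron_feasible(A, b) is None:
        return QPResult("infeasible", None, None)

    G = A @ A.T
    scale = max(1.0, float(np.abs(b).max()))

    def dual(lam: np.ndarray) -> tuple[float, np.ndarray]:
        Gl = G @ lam
        return 0.25 * lam @ Gl + b @ lam, 0.5 * Gl + b

    k = A.shape[0]
    res = minimize(
        dual,
        np.zeros(k),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * k,
        options={"maxiter": 2000, "ftol": 1e-16, "gtol": 1e-12 * scale},
    )
    lam = np.maximum(res.x, 0.0)
    m = -0.5 * A.T @ lam

    # active-set polish: least-norm solution of the tight constraints
    resid = A @ m - b
    act = np.where(resid > -1e-6 * scale)[0]
    if act.size:
        A_act, b_act = A[act], b[act]
        m_pol = A_act.T @ np.linalg.lstsq(A_act @ A_act.T, b_act, rcond=None)[0]
        feas_tol = 1e-8 * scale
        if np.all(A @ m_pol <= b + feas_tol) and (m_pol @ m_pol <= m @ m + feas_tol):
            m = m_pol
    return QPResult("optimal", m, float(m @ m))
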
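"""Probabilistic metabolic optimization (PMO).

Finds the most probable point of the steady-state thermodynamic space: the
``m`` of smallest norm (hence the ``t`` of highest prior density) such that

* some flux distribution satisfies steady state and bounds,
* every thermodynamically constrained reaction carries non-zero flux in
  the direction of negative reaction energy (second law, with a strict
  margin ``epsilon``),
* ``t`` lies inside the confidence ellipsoid.

The discrete degrees of freedom are the reaction directions.  We solve the
mixed problem exactly with branch-and-bound over direction assignments:
each node relaxes the unassigned directions, bounds the objective by the
minimum-norm point of the assigned sign constraints (a convex QP), and
checks steady-state feasibility of the partial assignment by LP.  This is
exact at the network sizes this package targets; the node bound is
monotone, so pruning never discards the optimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._lp import steady_state_lp
from ._qp import min_norm_in_polyhedron
from .network import MetabolicNetwork
from .thermo import ThermoSpace, chi2_threshold

__all__ = [
    "PMOResult",
    "solve_pmo",
    "find_initial_points",
    "z_scores",
    "classify_anomalies",
]

logger = logging.getLogger(__name__)

#: Strict-inequality margin for the second law, kJ/mol.
DEFAULT_EPSILON = 0.1
#: Smallest flux magnitude counted as "non-zero", mmol/gDW/h.
DEFAULT_V_MIN = 1e-6

_TIE_TOL = 1e-9


@dataclass
class PMOResult:
    status: str  # "optimal" | "infeasible"
    m_star: np.ndarray | None = None
    t_star: np.ndarray | None = None
    v_star: np.ndarray | None = None
    objective: float | None = None
    signature: tuple[int, ...] | None = None
    z: np.ndarray | None = None
    reduced: bool = False


def _fixed_signs(
    network: MetabolicNetwork,
    direction_constraints: dict[str, int] | None,
    flux_constraints: dict[str, tuple[float, float]] | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-Gamma fixed direction (+1/-1/0) and effective flux bounds."""
    lb = network.lb.copy()
    ub = network.ub.copy()
    if flux_constraints:
        for rid, (lo, hi) in flux_constraints.items():
            j = network.reaction_index(rid)
            lb[j] = max(lb[j], lo)
            ub[j] = min(ub[j], hi)
            if lb[j] > ub[j]:
                raise ValueError(f"contradictory flux constraints on {rid}")
    signs = np.zeros(network.n_gamma, dtype=int)
    for k, j in enumerate(network.gamma):
        if lb[j] >= 0:
            signs[k] = 1
        elif ub[j] <= 0:
            signs[k] = -1
    if direction_constraints:
        for rid, s in direction_constraints.items():
            j = network.reaction_index(rid)
            if j not in network.gamma:
                raise ValueError(f"{rid} is not thermodynamically constrained")
            k = network.gamma.index(j)
            if signs[k] and signs[k] != s:
                raise ValueError(f"direction constraint on {rid} conflicts with bounds")
            signs[k] = int(np.sign(s))
    return signs, lb, ub


def _direction_rows(
    W: np.ndarray, mu: np.ndarray, assigned: dict[int, int], epsilon: float,
    margins: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear rows ``s_k (mu_k + W_k m) <= -eps`` for assigned directions."""
    if not assigned:
        return np.zeros((0, W.shape[1])), np.zeros(0)
    ks = sorted(assigned)
    s = np.array([assigned[k] for k in ks], dtype=float)
    A = s[:, None] * W[ks]
    b = -epsilon - s * mu[ks]
    if margins is not None:
        b = b - margins[ks]
    return A, b


def _orthant_lp(
    network: MetabolicNetwork,
    lb: np.ndarray,
    ub: np.ndarray,
    assigned: dict[int, int],
    v_min: float,
    objective: np.ndarray | None = None,
):
    extra_lb, extra_ub = {}, {}
    for k, s in assigned.items():
        j = network.gamma[k]
        if s > 0:
            extra_lb[j] = v_min
        else:
            extra_ub[j] = -v_min
    return steady_state_lp(
        network.S, lb, ub, c=objective, extra_lb=extra_lb, extra_ub=extra_ub
    )


def _sig_key(sig: tuple[int, ...]) -> tuple[int, ...]:
    # lexicographic order with forward (+1) before backward (-1)
    return tuple(0 if s > 0 else 1 for s in sig)


def solve_pmo(
    network: MetabolicNetwork,
    space: ThermoSpace,
    direction_constraints: dict[str, int] | None = None,
    flux_constraints: dict[str, tuple[float, float]] | None = None,
    epsilon: float = DEFAULT_EPSILON,
    v_min: float = DEFAULT_V_MIN,
    reduced: bool = False,
    interior_margins: np.ndarray | None = None,
) -> PMOResult:
    """Most probable thermodynamic state under steady-state constraints.

    With ``reduced=True`` the search runs in the reduced reaction-energy
    coordinates (used to seed the sampler); otherwise in the full joint
    coordinates, so the result includes concentrations and standard
    energies.  Ties between equal-objective orthants break toward the
    lexicographically smallest direction signature.
    """
    gamma = network.n_gamma
    if reduced:
        W = space.Q_r
        mu = space.mu_r
        chi2 = space.chi2_r
    else:
        W = space.Q[space.n_mets + gamma :, :]  # rows mapping m -> dgr
        mu = space.mu_r
        chi2 = space.chi2
    fixed, lb, ub = _fixed_signs(network, direction_constraints, flux_constraints)

    best: dict = {"obj": np.inf, "sig": None, "m": None}
    order = [k for k in range(gamma) if fixed[k] == 0]
    base = {k: int(fixed[k]) for k in range(gamma) if fixed[k] != 0}

    def recurse(assigned: dict[int, int], depth: int) -> None:
        lp = _orthant_lp(network, lb, ub, assigned, v_min)
        if not lp.optimal:
            return
        A, b = _direction_rows(W, mu, assigned, epsilon, interior_margins)
        qp = min_norm_in_polyhedron(A, b)
        if qp.status != "optimal" or qp.objective > chi2 + 1e-9:
            return
        if qp.objective > best["obj"] + _TIE_TOL:
            return
        if depth == len(order):
            sig = tuple(assigned[k] for k in range(gamma))
            if qp.objective < best["obj"] - _TIE_TOL or (
                best["sig"] is None or _sig_key(sig) < _sig_key(best["sig"])
            ):
                if qp.objective < best["obj"]:
                    best["obj"] = qp.objective
                best["sig"] = sig
                best["m"] = qp.m
            return
        k = order[depth]
        for s in (1, -1):
            nxt = dict(assigned)
            nxt[k] = s
            recurse(nxt, depth + 1)

    recurse(dict(base), 0)

    if best["sig"] is None:
        return PMOResult(status="infeasible", reduced=reduced)
    assigned = {k: best["sig"][k] for k in range(gamma)}
    # flux witness: maximize the minimum directed slack for numerical margin
    lp = _orthant_lp(network, lb, ub, assigned, v_min)
    m_star = best["m"]
    result = PMOResult(
        status="optimal",
        m_star=m_star,
        v_star=lp.x,
        objective=float(best["obj"]),
        signature=best["sig"],
        reduced=reduced,
    )
    if not reduced:
        t_star = space.to_t(m_star)
        result.t_star = t_star
        result.z = z_scores(t_star, space)
    return result


@dataclass
class InitialPoint:
    m_r: np.ndarray
    signature: tuple[int, ...]
    margin: float


def find_initial_points(
    network: MetabolicNetwork,
    space: ThermoSpace,
    epsilon: float = DEFAULT_EPSILON,
    v_min: float = DEFAULT_V_MIN,
) -> list[InitialPoint]:
    """Over-dispersed, strictly interior chain starts in reduced coordinates.

    For each reversible constrained reaction, flux maximization and
    minimization LPs propose two direction assignments; PMO completes each
    into a feasible orthant, and a bisection on a joint interiority margin
    pushes the point away from both the sign constraints and the ellipsoid
    boundary.  Duplicate orthants are merged.  The unconstrained PMO
    orthant is always included, so irreversible-only networks still get
    one start.
    """
    proposals: list[dict[str, int]] = [{}]
    for j in network.gamma:
        if not network.is_reversible(j):
            continue
        for sense in (-1.0, 1.0):
            c = np.zeros(network.n_reactions)
            c[j] = sense
            lp = steady_state_lp(network.S, network.lb, network.ub, c=c)
            if not lp.optimal:
                continue
            cons = {
                network.reaction_ids[jj]: (1 if lp.x[jj] > 0 else -1)
                for jj in network.gamma
                if abs(lp.x[jj]) >= v_min
            }
            if cons:
                proposals.append(cons)

    points: dict[tuple[int, ...], InitialPoint] = {}
    for cons in proposals:
        base = solve_pmo(
            network, space, direction_constraints=cons, epsilon=epsilon,
            v_min=v_min, reduced=True,
        )
        if base.status != "optimal":
            continue
        sig = base.signature
        if sig in points:
            continue
        m, margin = _interior_point(network, space, sig, epsilon, v_min)
        if m is None:
            continue
        points[sig] = InitialPoint(m_r=m, signature=sig, margin=margin)
    if not points:
        raise RuntimeError(
            "no thermodynamically feasible orthant found; "
            "run the structural assessment to locate inconsistencies"
        )
    return [points[s] for s in sorted(points, key=_sig_key)]


def _interior_point(
    network: MetabolicNetwork,
    space: ThermoSpace,
    signature: tuple[int, ...],
    epsilon: float,
    v_min: float,
) -> tuple[np.ndarray | None, float]:
    """Chebyshev-like interiority: maximize a margin on signs and ellipsoid."""
    W, mu, chi2 = space.Q_r, space.mu_r, space.chi2_r
    assigned = dict(enumerate(signature))
    row_scale = np.maximum(np.linalg.norm(W, axis=1), 1e-12)

    def try_margin(delta: float):
        A, b = _direction_rows(W, mu, assigned, epsilon, delta * row_scale)
        qp = min_norm_in_polyhedron(A, b)
        if qp.status != "optimal":
            return None
        radius = np.sqrt(chi2) - delta
        if radius <= 0 or qp.objective > radius**2:
            return None
        return qp.m

    lo, hi = 0.0, float(np.sqrt(chi2))
    best_m = try_margin(0.0)
    if best_m is None:
        return None, 0.0
    best_d = 0.0
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        m = try_margin(mid)
        if m is not None:
            best_m, best_d, lo = m, mid, mid
        else:
            hi = mid
    return best_m, best_d


def z_scores(t_star: np.ndarray, space: ThermoSpace) -> np.ndarray:
    """Deviation of each component of ``t*`` from its prior mean in SDs.

    Components with zero prior variance get 0 when the value sits at the
    mean and ``inf`` otherwise (a flagged impossibility).
    """
    sd = np.sqrt(np.clip(np.diag(space.Sigma_t), 0.0, None))
    diff = np.asarray(t_star, dtype=float) - space.mu_t
    z = np.zeros_like(diff)
    nz = sd > 0
    z[nz] = diff[nz] / sd[nz]
    z[~nz & (np.abs(diff) > 1e-9)] = np.inf
    return z


@dataclass
class Anomaly:
    metabolite_id: str
    z: float
    concentration: float  # molar
    reason: str = field(default="z-score")


def classify_anomalies(
    z: np.ndarray,
    concentrations: np.ndarray,
    network: MetabolicNetwork,
    theta: float = 1.0,
    conc_limit: float = 0.010,
    intracellular: str = "c",
) -> list[Anomaly]:
    """Flag metabolites whose predicted state is implausible.

    A metabolite is anomalous when its z-score magnitude exceeds ``theta``
    (conservatively 1, because mode-based predictions underestimate true
    deviations), or when a non-intracellular metabolite is predicted at or
    above 10 mM.  Anomalies point at knowledge gaps: substrate channeling,
    wrong irreversibilities, bad standard-energy estimates.
    """
    out: list[Anomaly] = []
    for i, mid in enumerate(network.metabolite_ids):
        zi = float(z[i])
        ci = float(concentrations[i])
        if abs(zi) > theta:
            out.append(Anomaly(mid, zi, ci, reason="z-score"))
        elif network.compartments[i] != intracellular and ci >= conc_limit:
            out.append(Anomaly(mid, zi, ci, reason="extracellular concentration"))
    return out
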
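"""Flux sampling with the thermodynamic orthant distribution as prior.

Once the thermodynamic sampler has estimated how probable each
combination of reaction directions is, the flux space is explored orthant
by orthant: each selected direction assignment fixes the sign (and a
minimum magnitude) of every constrained reaction, turning the steady-state
flux space into a convex polytope that Coordinate Hit-and-Run with
Rounding samples uniformly.  Pooling per-orthant draws in proportion to
orthant probability approximates the thermodynamics-weighted flux
distribution; thermodynamically infeasible cycles never appear because
their orthants carry zero probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import null_space

from ._lp import solve_lp
from .network import MetabolicNetwork
from .pmo import DEFAULT_V_MIN

__all__ = [
    "Polytope",
    "FluxSamples",
    "build_orthant_polytope",
    "chrr_sample",
    "sample_flux_mixture",
    "call_directions",
]

logger = logging.getLogger(__name__)

#: Feasible widths below this are treated as collapsed dimensions.
DEGENERATE_WIDTH = 1e-9


@dataclass
class Polytope:
    """Affine-parametrized polytope ``{v = v0 + N x : A x <= b}``."""

    v0: np.ndarray  # interior point in ambient coordinates
    N: np.ndarray  # null-space basis (ambient_dim x d)
    A: np.ndarray  # inequality rows in x coordinates
    b: np.ndarray
    rounding: np.ndarray | None = None  # x = rounding @ y

    @classmethod
    def from_bounded_system(
        cls,
        A_eq: np.ndarray | None,
        b_eq: np.ndarray | None,
        lb: np.ndarray,
        ub: np.ndarray,
    ) -> "Polytope":
        """Polytope ``{v : A_eq v = b_eq, lb <= v <= ub}``.

        Finds a Chebyshev-style interior point by maximizing the common
        slack to the bounds, then parametrizes the equality null space.
        """
        lb = np.asarray(lb, dtype=float)
        ub = np.asarray(ub, dtype=float)
        n = len(lb)
        slack_dims = (ub - lb) > DEGENERATE_WIDTH
        # variables (v, t): maximize t with lb + t*w <= v <= ub - t*w
        c = np.zeros(n + 1)
        c[-1] = -1.0
        rows, rhs = [], []
        for i in range(n):
            w = 1.0 if slack_dims[i] else 0.0
            r = np.zeros(n + 1)
            r[i], r[-1] = -1.0, w
            rows.append(r)
            rhs.append(-lb[i])
            r = np.zeros(n + 1)
            r[i], r[-1] = 1.0, w
            rows.append(r)
            rhs.append(ub[i])
        Aeq_ext = None
        beq = None
        if A_eq is not None and len(A_eq):
            Aeq_ext = np.hstack([A_eq, np.zeros((A_eq.shape[0], 1))])
            beq = np.asarray(b_eq, dtype=float)
        res = solve_lp(
            c,
            A_eq=Aeq_ext,
            b_eq=beq,
            A_ub=np.array(rows),
            b_ub=np.array(rhs),
            bounds=[(None, None)] * n + [(0.0, None)],
        )
        if not res.optimal:
            raise ValueError("polytope is empty")
        v0 = res.x[:n]
        if A_eq is not None and len(A_eq):
            N = null_space(np.asarray(A_eq, dtype=float))
        else:
            N = np.eye(n)
        if N.shape[1] == 0:
            N = np.zeros((n, 0))
        A = np.vstack([N, -N])
        b = np.concatenate([ub - v0, v0 - lb])
        return cls(v0=v0, N=N, A=A, b=b)

    @property
    def dim(self) -> int:
        return self.N.shape[1]

    def to_ambient(self, x: np.ndarray) -> np.ndarray:
        return self.v0 + x @ self.N.T

    def contains(self, v: np.ndarray, tol: float = 1e-8) -> bool:
        x, *_ = np.linalg.lstsq(self.N, v - self.v0, rcond=None)
        return bool(np.all(self.A @ x <= self.b + tol))


def build_orthant_polytope(
    network: MetabolicNetwork,
    signature: tuple[int, ...],
    v_min: float = DEFAULT_V_MIN,
) -> Polytope:
    """Steady-state flux polytope restricted to one direction orthant.

    Each constrained reaction's bounds are intersected with its sign
    (magnitude at least ``v_min``, the same threshold the thermodynamic
    sampler uses for "non-zero flux").
    """
    lb = network.lb.copy()
    ub = network.ub.copy()
    for k, j in enumerate(network.gamma):
        if signature[k] > 0:
            lb[j] = max(lb[j], v_min)
        else:
            ub[j] = min(ub[j], -v_min)
        if lb[j] > ub[j]:
            raise ValueError(
                f"orthant flips reaction {network.reaction_ids[j]} against its bounds"
            )
    try:
        return Polytope.from_bounded_system(
            network.S, np.zeros(network.n_metabolites), lb, ub
        )
    except ValueError as exc:
        raise RuntimeError(
            "orthant polytope empty despite feasible signature"
        ) from exc


def _coordinate_interval(
    A: np.ndarray, resid: np.ndarray, i: int
) -> tuple[float, float]:
    """Feasible step range along coordinate ``i`` given slack ``resid = b - A x``."""
    col = A[:, i]
    lo, hi = -np.inf, np.inf
    pos = col > 1e-12
    neg = col < -1e-12
    if pos.any():
        hi = float(np.min(resid[pos] / col[pos]))
    if neg.any():
        lo = float(np.max(resid[neg] / col[neg]))
    return lo, hi


def chrr_sample(
    polytope: Polytope,
    n: int,
    rng: np.random.Generator,
    warmup: int | None = None,
    rounding_rounds: int = 2,
) -> np.ndarray:
    """Asymptotically uniform draws by Coordinate Hit-and-Run with Rounding.

    The rounding transform is estimated iteratively: short pilot runs
    provide a sample covariance whose Cholesky factor approximates the
    inertial ellipsoid of the body, and coordinate moves are made in the
    transformed (well-rounded) basis.  Dimensions with numerically zero
    feasible width are collapsed with a warning.  Deterministic given the
    generator state.
    """
    d = polytope.dim
    if d == 0:
        return np.tile(polytope.v0, (n, 1))
    A, b = polytope.A, polytope.b
    T = np.eye(d)

    def run(A_t, x, steps, collect=None):
        resid = b - A_t @ x
        active = [
            i
            for i in range(d)
            if np.ptp(np.array(_coordinate_interval(A_t, resid, i))) > DEGENERATE_WIDTH
            or np.isinf(_coordinate_interval(A_t, resid, i)).any()
        ]
        if len(active) < d:
            logger.warning(
                "collapsing %d degenerate polytope dimension(s)", d - len(active)
            )
        if not active:
            if collect is not None:
                collect.extend([x.copy()] * steps)
            return x
        for s in range(steps):
            i = active[int(rng.integers(len(active)))]
            resid = b - A_t @ x
            lo, hi = _coordinate_interval(A_t, resid, i)
            if not np.isfinite(lo) or not np.isfinite(hi) or hi - lo < 0:
                continue
            x = x.copy()
            x[i] += rng.uniform(lo, hi)
            if collect is not None:
                collect.append(x)
        return x

    x = np.zeros(d)
    for _ in range(rounding_rounds):
        pilot: list[np.ndarray] = []
        x = run(A @ T, x, steps=max(200, 20 * d), collect=pilot)
        P = np.array(pilot)
        if len(P) < 2 * d:
            break
        cov = np.cov(P.T).reshape(d, d)
        w, V = np.linalg.eigh(cov)
        w = np.clip(w, max(w.max(), 1e-30) * 1e-12, None)
        L = V * np.sqrt(w)
        T_new = T @ L
        x = np.linalg.solve(L, x)
        T = T_new

    warm = warmup if warmup is not None else max(100, 10 * d)
    A_t = A @ T
    x = run(A_t, x, warm)
    draws: list[np.ndarray] = []
    x = run(A_t, x, n, collect=draws)
    X = np.array(draws)
    if len(X) < n:  # degenerate body: pad with current point
        pad = np.tile(x, (n - len(X), 1)) if len(X) else np.tile(x, (n, 1))
        X = np.vstack([X, pad]) if len(X) else pad
    return polytope.to_ambient(X @ T.T)


@dataclass
class FluxSamples:
    """Pooled flux draws tagged with their source orthant."""

    fluxes: np.ndarray  # (n_total, n_reactions)
    orthants: list[tuple[int, ...]]  # per draw
    counts: dict = field(default_factory=dict)  # signature -> n draws

    def to_frame(self, network: MetabolicNetwork) -> pd.DataFrame:
        df = pd.DataFrame(self.fluxes, columns=network.reaction_ids)
        df.insert(0, "orthant", [str(o) for o in self.orthants])
        return df


def _allocate(probs: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder allocation of ``total`` draws (deterministic)."""
    raw = probs * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    if rem > 0:
        frac = raw - base
        order = np.lexsort((np.arange(len(frac)), -frac))
        base[order[:rem]] += 1
    return base


def sample_flux_mixture(
    network: MetabolicNetwork,
    orthant_table: pd.DataFrame,
    n_orthants: int,
    n_total: int,
    rng: np.random.Generator,
    v_min: float = DEFAULT_V_MIN,
) -> FluxSamples:
    """Probability-weighted mixture of per-orthant uniform flux samples.

    ``n_orthants`` orthants are drawn without replacement with probability
    proportional to their estimated mass; each receives a number of CHRR
    draws proportional to its (renormalized) probability, allocated by
    largest remainder so the total is exactly ``n_total``.
    """
    if orthant_table.empty:
        raise ValueError("orthant table is empty")
    sigs = list(orthant_table["signature"])
    probs = orthant_table["probability"].to_numpy(dtype=float)
    probs = probs / probs.sum()
    k = min(n_orthants, len(sigs))
    idx = rng.choice(len(sigs), size=k, replace=False, p=probs)
    sel_probs = probs[idx] / probs[idx].sum()
    alloc = _allocate(sel_probs, n_total)

    all_fluxes = []
    all_tags: list[tuple[int, ...]] = []
    counts: dict = {}
    for i, n_draws in zip(idx, alloc):
        if n_draws == 0:
            continue
        sig = tuple(sigs[i])
        poly = build_orthant_polytope(network, sig, v_min)
        draws = chrr_sample(poly, int(n_draws), rng)
        all_fluxes.append(draws)
        all_tags.extend([sig] * int(n_draws))
        counts[sig] = int(n_draws)
    return FluxSamples(
        fluxes=np.vstack(all_fluxes), orthants=all_tags, counts=counts
    )


def call_directions(
    samples: np.ndarray,
    threshold: float = 0.95,
) -> list[str]:
    """Direction call per column: forward / backward / reversible.

    A reaction is called irreversible when at least ``threshold`` of the
    samples share a sign.  Works on flux samples directly, or on negated
    reaction-energy samples (a negative energy means forward flux).
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.size == 0:
        raise ValueError("no samples")
    frac_fwd = np.mean(samples > 0, axis=0)
    frac_bwd = np.mean(samples < 0, axis=0)
    out = []
    for f, bwd in zip(frac_fwd, frac_bwd):
        if f >= threshold:
            out.append("forward")
        elif bwd >= threshold:
            out.append("backward")
        else:
            out.append("reversible")
    return out
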
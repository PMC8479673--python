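"""Synthetic networks, priors and ground-truth oracles.

Every stage of the package is testable on small generated fixtures: toy
topologies (linear chains, branch points, cycles, a two-step pathway with a
stoichiometrically redundant shortcut, an irreversibility-conflict cycle,
and random networks), log-normal concentration priors around a
physiological 0.1 mM, and group-contribution-style standard-energy priors
whose covariance can be made rank-deficient on purpose.

Two independent oracles provide ground truth for the samplers:

* :func:`rejection_oracle` draws from the exact prior, maps the draws
  through the energy decomposition and keeps those whose reaction-direction
  orthant admits a steady-state flux distribution — brute force, but exact
  in distribution.
* :func:`enumerate_orthants` walks all ``2^gamma`` sign vectors, checks
  steady-state feasibility by LP, and integrates the truncated Gaussian
  mass over each orthant with quasi-Monte-Carlo.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from ._lp import steady_state_lp
from .network import MetabolicNetwork, ThermoPriors, select_thermo_reactions
from .thermo import ThermoSpace, build_joint

__all__ = [
    "FixtureSpec",
    "make_network",
    "rejection_oracle",
    "enumerate_orthants",
    "OracleResult",
]

TOPOLOGIES = ("chain", "branch", "cycle", "triangle", "forced_cycle", "random")

#: Default ln-concentration prior: 0.1 mM with a 1-log-unit spread.
DEFAULT_MU_LN_C = float(np.log(1e-4))
DEFAULT_SD_LN_C = 1.0


@dataclass
class FixtureSpec:
    """Recipe for a synthetic network plus priors.

    ``dg0_rank_deficient`` builds the standard-energy covariance from fewer
    latent group contributions than reactions, emulating correlated
    estimator errors; the ``triangle`` topology additionally ties the
    shortcut's standard energy to the sum of the two pathway steps, so the
    reduced energy covariance loses a full rank.
    """

    topology: str = "chain"
    n_reactions: int = 3
    seed: int = 0
    reversible: bool | None = None  # None: topology default
    mu_ln_c: float = DEFAULT_MU_LN_C
    sd_ln_c: float = DEFAULT_SD_LN_C
    dg0_mu_scale: float = 5.0  # kJ/mol spread of mean standard energies
    dg0_sd: float = 4.0  # kJ/mol marginal sd of standard energies
    dg0_rank_deficient: bool = False
    flux_bound: float = 10.0
    extra: dict = field(default_factory=dict)


def make_network(spec: FixtureSpec) -> tuple[MetabolicNetwork, ThermoPriors]:
    """Build the network and priors described by ``spec`` (deterministic)."""
    if spec.topology not in TOPOLOGIES:
        raise ValueError(f"unknown topology {spec.topology!r}")
    rng = np.random.default_rng(spec.seed)
    builder = {
        "chain": _chain,
        "branch": _branch,
        "cycle": _cycle,
        "triangle": _triangle,
        "forced_cycle": _forced_cycle,
        "random": _random_net,
    }[spec.topology]
    network, group_map = builder(spec, rng)
    network.gamma = select_thermo_reactions(
        network, drop_blocked=spec.topology != "forced_cycle"
    )
    priors = _make_priors(spec, network, group_map, rng)
    return network, priors


# ---------------------------------------------------------------------------
# topology builders: return (network, group_map) where group_map optionally
# expresses each Gamma reaction's standard energy as a combination of latent
# groups (None: independent per reaction)
# ---------------------------------------------------------------------------


def _bounds(spec: FixtureSpec, reversible: bool) -> tuple[float, float]:
    B = spec.flux_bound
    return (-B, B) if reversible else (0.0, B)


def _net(S, lb, ub, rids, mids) -> MetabolicNetwork:
    return MetabolicNetwork(
        S=np.asarray(S, dtype=float),
        lb=np.asarray(lb, dtype=float),
        ub=np.asarray(ub, dtype=float),
        reaction_ids=list(rids),
        metabolite_ids=list(mids),
    )


def _chain(spec: FixtureSpec, rng) -> tuple[MetabolicNetwork, None]:
    n = spec.n_reactions
    if n < 1:
        raise ValueError("chain needs >= 1 reaction")
    mids = [f"M{i}" for i in range(n + 1)]
    rids = [f"R{i}" for i in range(1, n + 1)] + ["EX_M0", f"EX_M{n}"]
    S = np.zeros((n + 1, n + 2))
    for j in range(n):
        S[j, j] = -1.0
        S[j + 1, j] = 1.0
    S[0, n] = 1.0  # EX_M0: -> M0
    S[n, n + 1] = -1.0  # EX_Mn: Mn ->
    rev = True if spec.reversible is None else spec.reversible
    lo, hi = _bounds(spec, rev)
    lb = [lo] * n + [-spec.flux_bound] * 2
    ub = [hi] * n + [spec.flux_bound] * 2
    return _net(S, lb, ub, rids, mids), None


def _branch(spec: FixtureSpec, rng) -> tuple[MetabolicNetwork, None]:
    # A -> B and A -> C with exchanges on all three
    mids = ["A", "B", "C"]
    rids = ["R1", "R2", "EX_A", "EX_B", "EX_C"]
    S = np.array(
        [
            [-1, -1, 1, 0, 0],
            [1, 0, 0, -1, 0],
            [0, 1, 0, 0, -1],
        ],
        dtype=float,
    )
    rev = True if spec.reversible is None else spec.reversible
    lo, hi = _bounds(spec, rev)
    B = spec.flux_bound
    return _net(S, [lo, lo, -B, -B, -B], [hi, hi, B, B, B], rids, mids), None


def _cycle(spec: FixtureSpec, rng) -> tuple[MetabolicNetwork, None]:
    # A -> B -> C -> A, exchange on A only; fully reversible by default
    mids = ["A", "B", "C"]
    rids = ["R1", "R2", "R3", "EX_A"]
    S = np.array(
        [
            [-1, 0, 1, 1],
            [1, -1, 0, 0],
            [0, 1, -1, 0],
        ],
        dtype=float,
    )
    rev = True if spec.reversible is None else spec.reversible
    lo, hi = _bounds(spec, rev)
    B = spec.flux_bound
    return _net(S, [lo] * 3 + [-B], [hi] * 3 + [B], rids, mids), None


def _triangle(spec: FixtureSpec, rng) -> tuple[MetabolicNetwork, np.ndarray | None]:
    # Two-step pathway A -> B -> C plus the direct shortcut A -> C; the
    # shortcut's column equals the sum of the two steps, so its reaction
    # energy is their sum in every state.
    mids = ["A", "B", "C"]
    rids = ["R1", "R2", "R3", "EX_A", "EX_C"]
    S = np.array(
        [
            [-1, 0, -1, 1, 0],
            [1, -1, 0, 0, 0],
            [0, 1, 1, 0, -1],
        ],
        dtype=float,
    )
    rev = True if spec.reversible is None else spec.reversible
    lo, hi = _bounds(spec, rev)
    B = spec.flux_bound
    net = _net(S, [lo] * 3 + [-B, -B], [hi] * 3 + [B, B], rids, mids)
    group_map = None
    if spec.dg0_rank_deficient:
        # latent contributions g1, g2; dg0 = (g1, g2, g1 + g2)
        group_map = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    return net, group_map


def _forced_cycle(spec: FixtureSpec, rng) -> tuple[MetabolicNetwork, None]:
    # Irreversibility-conflict motif: a loop of irreversible conversions
    # A -> B -> C -> A that must run whenever any flux flows.  Echoes the
    # classic curation case where a cycle of irreversible reactions (e.g.
    # acyl-transfer/kinase loops in propionate metabolism) is forced active.
    mids = ["A", "B", "C"]
    rids = ["R1", "R2", "R3", "EX_A"]
    S = np.array(
        [
            [-1, 0, 1, 1],
            [1, -1, 0, 0],
            [0, 1, -1, 0],
        ],
        dtype=float,
    )
    B = spec.flux_bound
    rev = False if spec.reversible is None else spec.reversible
    lo, hi = _bounds(spec, rev)
    net = _net(S, [lo] * 3 + [-B], [hi] * 3 + [B], rids, mids)
    # standard energies respect the loop identity dg1 + dg2 + dg3 = 0, so
    # the cycle can never be favorable all the way around — the fixture is
    # thermodynamically inconsistent by construction
    group_map = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, -1.0]])
    return net, group_map


def _random_net(spec: FixtureSpec, rng) -> tuple[MetabolicNetwork, None]:
    """Chain backbone plus random shortcut reactions between metabolites.

    Regenerates (deterministically) until no internal reaction is blocked,
    so every fixture has a usable thermodynamically constrained set.
    """
    n = spec.n_reactions
    if n < 2:
        raise ValueError("random topology needs >= 2 reactions")
    n_back = max(2, n // 2)
    n_extra = n - n_back
    n_mets = n_back + 1
    for attempt in range(50):
        sub = np.random.default_rng((spec.seed, attempt))
        S = np.zeros((n_mets, n + 2))
        for j in range(n_back):
            S[j, j] = -1.0
            S[j + 1, j] = 1.0
        for j in range(n_extra):
            a, b = sub.choice(n_mets, size=2, replace=False)
            S[a, n_back + j] = -1.0
            S[b, n_back + j] = 1.0
        S[0, n] = 1.0
        S[n_mets - 1, n + 1] = -1.0
        B = spec.flux_bound
        rev = sub.random(n) < (0.7 if spec.reversible is None else float(spec.reversible))
        lb = np.where(rev, -B, 0.0).tolist() + [-B, -B]
        ub = [B] * (n + 2)
        mids = [f"M{i}" for i in range(n_mets)]
        rids = [f"R{j}" for j in range(1, n + 1)] + ["EX_in", "EX_out"]
        net = _net(S, lb, ub, rids, mids)
        try:
            gamma = select_thermo_reactions(net, drop_blocked=True)
        except Exception:
            continue
        if len(gamma) == n:  # no blocked internals
            return net, None
    raise RuntimeError("could not generate an unblocked random fixture")


def _make_priors(
    spec: FixtureSpec, network: MetabolicNetwork, group_map, rng
) -> ThermoPriors:
    m = network.n_metabolites
    gamma = network.n_gamma
    mu_c = np.full(m, spec.mu_ln_c)
    Sigma_c = np.eye(m) * spec.sd_ln_c**2
    if group_map is not None:
        n_groups = group_map.shape[1]
        g_mu = rng.normal(0.0, spec.dg0_mu_scale, size=n_groups)
        g_sd = np.full(n_groups, spec.dg0_sd / np.sqrt(2))
        mu_0 = group_map @ g_mu
        Sigma_0 = (group_map * g_sd**2) @ group_map.T
    elif spec.dg0_rank_deficient and gamma > 1:
        n_groups = max(1, gamma - 1)
        G = rng.normal(0.0, 1.0, size=(gamma, n_groups))
        mu_0 = rng.normal(0.0, spec.dg0_mu_scale, size=gamma)
        Sigma_0 = G @ G.T * (spec.dg0_sd**2 / n_groups)
    else:
        mu_0 = rng.normal(0.0, spec.dg0_mu_scale, size=gamma)
        Sigma_0 = np.eye(gamma) * spec.dg0_sd**2
    return ThermoPriors(mu_c=mu_c, Sigma_c=Sigma_c, mu_0=mu_0, Sigma_0=Sigma_0)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


@dataclass
class OracleResult:
    """Ground-truth orthant table and accepted prior draws."""

    table: pd.DataFrame  # columns: signature, count/mass, probability, feasible
    dg_samples: np.ndarray  # accepted reaction-energy draws
    ln_c_samples: np.ndarray | None
    dg0_samples: np.ndarray | None
    acceptance_rate: float

    def probability(self, signature: tuple[int, ...]) -> float:
        row = self.table[self.table["signature"] == signature]
        return float(row["probability"].iloc[0]) if len(row) else 0.0


def _required_signs(network: MetabolicNetwork) -> np.ndarray:
    """Fixed direction per Gamma reaction: +1/-1 if irreversible, 0 if free."""
    signs = np.zeros(network.n_gamma, dtype=int)
    for k, j in enumerate(network.gamma):
        if network.lb[j] >= 0:
            signs[k] = 1
        elif network.ub[j] <= 0:
            signs[k] = -1
    return signs


def _orthant_feasible_lp(
    network: MetabolicNetwork, signs: np.ndarray, v_min: float
) -> bool:
    extra_lb, extra_ub = {}, {}
    for k, j in enumerate(network.gamma):
        if signs[k] > 0:
            extra_lb[j] = v_min
        else:
            extra_ub[j] = -v_min
    res = steady_state_lp(
        network.S, network.lb, network.ub, extra_lb=extra_lb, extra_ub=extra_ub
    )
    return res.optimal


def rejection_oracle(
    network: MetabolicNetwork,
    space: ThermoSpace,
    n_draws: int = 1_000_000,
    rng: np.random.Generator | None = None,
    v_min: float = 1e-6,
    keep_conditionals: bool = True,
) -> OracleResult:
    """Brute-force draws from the steady-state thermodynamic space.

    Draws ``(ln c, dgr0)`` from the exact prior, maps them to reaction
    energies, and keeps draws that (i) fall inside the reduced confidence
    ball, (ii) respect irreversibility signs and (iii) land in an orthant
    with a steady-state flux distribution (LP-checked, cached per
    signature).  The retained draws follow the samplers' target
    distribution exactly, so their orthant frequencies and conditional
    moments are ground truth.
    """
    if network.n_gamma > 12:
        raise ValueError("rejection oracle limited to gamma <= 12")
    rng = np.random.default_rng(0) if rng is None else rng
    q = space.q
    z = rng.standard_normal((n_draws, q))
    t = space.mu_t[None, :] + z @ space.Q.T
    ln_c, dg0, dg = space.split_t(t)
    m_r = space.reduced_coords(dg)
    keep = np.einsum("ij,ij->i", m_r, m_r) <= space.chi2_r
    req = _required_signs(network)
    signs = np.where(dg < 0, 1, -1).astype(int)  # direction implied by energy
    for k in np.nonzero(req)[0]:
        keep &= signs[:, k] == req[k]
    keep &= np.all(dg != 0.0, axis=1)
    signs = signs[keep]
    ln_c, dg0, dg = ln_c[keep], dg0[keep], dg[keep]

    feas_cache: dict[tuple[int, ...], bool] = {}
    uniq, inv = np.unique(signs, axis=0, return_inverse=True)
    feas_mask = np.zeros(len(uniq), dtype=bool)
    for i, s in enumerate(uniq):
        key = tuple(int(x) for x in s)
        if key not in feas_cache:
            feas_cache[key] = _orthant_feasible_lp(network, s, v_min)
        feas_mask[i] = feas_cache[key]
    accept = feas_mask[inv]
    n_acc = int(accept.sum())
    if n_acc < max(1, n_draws * 1e-5):
        raise RuntimeError(
            f"rejection oracle acceptance too low ({n_acc}/{n_draws})"
        )
    counts: dict[tuple[int, ...], int] = {}
    acc_inv = inv[accept]
    for i, s in enumerate(uniq):
        c = int(np.sum(acc_inv == i))
        if feas_mask[i] and c:
            counts[tuple(int(x) for x in s)] = c
    table = pd.DataFrame(
        {
            "signature": list(counts.keys()),
            "count": list(counts.values()),
        }
    )
    table["probability"] = table["count"] / n_acc
    table["feasible"] = True
    table = table.sort_values("probability", ascending=False).reset_index(drop=True)
    return OracleResult(
        table=table,
        dg_samples=dg[accept],
        ln_c_samples=ln_c[accept] if keep_conditionals else None,
        dg0_samples=dg0[accept] if keep_conditionals else None,
        acceptance_rate=n_acc / n_draws,
    )


def enumerate_orthants(
    network: MetabolicNetwork,
    space: ThermoSpace,
    n_points: int = 1 << 15,
    v_min: float = 1e-6,
    qmc_seed: int = 12345,
) -> pd.DataFrame:
    """Exhaustive orthant table with quasi-Monte-Carlo Gaussian masses.

    For each of the ``2^gamma`` sign vectors: steady-state feasibility by
    LP and the truncated-Gaussian mass of the orthant, integrated with a
    scrambled Sobol sequence in the reduced coordinates.  The
    ``probability`` column is normalized over feasible orthants.
    """
    gamma = network.n_gamma
    if gamma > 6:
        raise ValueError("exhaustive enumeration limited to gamma <= 6")
    sob = qmc.Sobol(d=space.q_r, scramble=True, seed=qmc_seed)
    u = sob.random(n_points)
    z = stats.norm.ppf(np.clip(u, 1e-12, 1 - 1e-12))
    inside = np.einsum("ij,ij->i", z, z) <= space.chi2_r
    dg = space.mu_r[None, :] + z[inside] @ space.Q_r.T
    signs = np.where(dg < 0, 1, -1).astype(int)
    req = _required_signs(network)

    rows = []
    for bits in range(1 << gamma):
        s = np.array([1 if (bits >> k) & 1 == 0 else -1 for k in range(gamma)])
        if np.any((req != 0) & (s != req)):
            continue
        feasible = _orthant_feasible_lp(network, s, v_min)
        mass = float(np.mean(np.all(signs == s[None, :], axis=1)))
        rows.append(
            {"signature": tuple(int(x) for x in s), "feasible": feasible, "mass": mass}
        )
    table = pd.DataFrame(rows)
    feas = table["feasible"]
    total = float(table.loc[feas, "mass"].sum())
    table["probability"] = np.where(feas, table["mass"] / max(total, 1e-300), 0.0)
    return table.sort_values("probability", ascending=False).reset_index(drop=True)
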
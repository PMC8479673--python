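"""Hit-and-Run MCMC over the steady-state thermodynamic space.

The target is the prior Gaussian restricted to the confidence ball and to
the reaction-direction orthants that admit a steady-state flux
distribution — a union of convex pieces that is neither convex nor, in
general, connected through high-probability regions.  Sampling runs in the
reduced coordinates ``m`` of the reaction energies (dimension ``q_r``),
where the target is a standard multivariate normal truncated to the ball
``||m||^2 <= chi2(q_r, alpha)``.

Each step draws a random ray through the current point, intersects it with
the ball and the sign constraints of irreversible reactions, splits the
chord at the zero crossings of the reaction energies, discards
sub-segments whose direction orthant fails the steady-state LP (cached per
signature), and samples the next point exactly from the 1-D truncated
normal restricted to the surviving segments.  Because the move samples the
exact conditional along the ray, the stationary distribution is the target
for any symmetric full-support ray distribution; convergence is adapted by
inflating ray components along poorly mixing dimensions without touching
the target.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special
from scipy.stats import truncnorm

from ._lp import steady_state_lp
from .network import MetabolicNetwork
from .thermo import ThermoSpace
from . import diagnostics as diag
from .pmo import DEFAULT_V_MIN, find_initial_points

__all__ = [
    "OrthantCache",
    "RaySegment",
    "SampleSet",
    "steady_state_feasible",
    "intersect_ray",
    "sample_step",
    "run_tfs",
    "adapt_parametrization",
    "sample_concentrations",
]

logger = logging.getLogger(__name__)

Signature = tuple[int, ...]

#: Zero crossings closer than this (in ray parameter) are merged.
CROSSING_MERGE_TOL = 1e-12


class OrthantCache:
    """Memoized steady-state feasibility per direction signature."""

    def __init__(self, network: MetabolicNetwork, v_min: float = DEFAULT_V_MIN):
        self.network = network
        self.v_min = v_min
        self._cache: dict[Signature, bool] = {}

    def feasible(self, signature: Signature) -> bool:
        hit = self._cache.get(signature)
        if hit is not None:
            return hit
        extra_lb, extra_ub = {}, {}
        for k, j in enumerate(self.network.gamma):
            if signature[k] > 0:
                extra_lb[j] = self.v_min
            else:
                extra_ub[j] = -self.v_min
        res = steady_state_lp(
            self.network.S,
            self.network.lb,
            self.network.ub,
            extra_lb=extra_lb,
            extra_ub=extra_ub,
        )
        self._cache[signature] = res.optimal
        return res.optimal

    def __len__(self) -> int:
        return len(self._cache)


def steady_state_feasible(
    network: MetabolicNetwork,
    signature: Signature,
    v_min: float = DEFAULT_V_MIN,
    cache: OrthantCache | None = None,
) -> bool:
    """Does the orthant admit a steady-state flux distribution?

    Pre-checks the fixed directions of irreversible reactions before
    spending an LP.
    """
    for k, j in enumerate(network.gamma):
        if signature[k] > 0 and network.ub[j] < v_min:
            return False
        if signature[k] < 0 and network.lb[j] > -v_min:
            return False
    cache = cache or OrthantCache(network, v_min)
    return cache.feasible(signature)


@dataclass
class RaySegment:
    a: float
    b: float
    signature: Signature
    feasible: bool
    log_weight: float  # log Gaussian mass; -inf when infeasible


def _fixed_direction_signs(network: MetabolicNetwork, v_min: float) -> np.ndarray:
    signs = np.zeros(network.n_gamma, dtype=int)
    for k, j in enumerate(network.gamma):
        if network.lb[j] >= -v_min:
            signs[k] = 1
        elif network.ub[j] <= v_min:
            signs[k] = -1
    return signs


def _signature_at(dg: np.ndarray) -> Signature:
    # flux direction implied by the energy: forward iff dg < 0
    return tuple(1 if g < 0 else -1 for g in dg)


def intersect_ray(
    space: ThermoSpace,
    cache: OrthantCache,
    m0: np.ndarray,
    direction: np.ndarray,
    fixed_signs: np.ndarray | None = None,
) -> list[RaySegment]:
    """Feasible segments of the ray ``m0 + s * direction``.

    The chord with the confidence ball comes from the quadratic formula;
    the sign constraints of irreversible reactions clip it; the zero
    crossings of the reaction energies split it into orthant segments,
    each tested against the steady-state LP cache.  The ray parameter of
    the current point (s=0) always lies in a feasible segment.
    """
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    mm = float(m0 @ m0)
    mu_s = float(m0 @ u)
    disc = mu_s**2 - (mm - space.chi2_r)
    if disc <= 0:
        raise ValueError("ray does not intersect the confidence ball interior")
    root = np.sqrt(disc)
    a, b = -mu_s - root, -mu_s + root
    if b - a < 1e-14:
        raise ValueError("degenerate chord")

    g0 = space.mu_r + space.Q_r @ m0  # energies at current point
    h = space.Q_r @ u  # energy gradient along the ray
    if fixed_signs is None:
        fixed_signs = _fixed_direction_signs(space.network, cache.v_min)

    # clip the chord by the sign constraints of irreversible reactions:
    # direction +1 requires dg_i < 0 along the whole admissible range
    for k in np.nonzero(fixed_signs)[0]:
        want_neg = fixed_signs[k] > 0
        gk, hk = g0[k], h[k]
        if abs(hk) < 1e-300:
            continue  # sign constant along the ray; holds at s=0
        s_star = -gk / hk
        if (hk > 0) == want_neg:
            b = min(b, s_star)
        else:
            a = max(a, s_star)
    if b - a < 1e-14:
        return [
            RaySegment(0.0, 0.0, _signature_at(g0), True, -np.inf)
        ]

    free = np.nonzero(fixed_signs == 0)[0]
    crossings = []
    for k in free:
        if abs(h[k]) < 1e-300:
            continue
        s_star = -g0[k] / h[k]
        if a < s_star < b:
            crossings.append(s_star)
    crossings.sort()
    merged: list[float] = []
    for s in crossings:
        if merged and s - merged[-1] < CROSSING_MERGE_TOL:
            continue
        merged.append(s)
    edges = [a] + merged + [b]

    loc = -mu_s  # 1-D target along the ray is N(loc, 1)
    segments: list[RaySegment] = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mid = 0.5 * (lo + hi)
        sig = _signature_at(g0 + mid * h)
        feas = cache.feasible(sig)
        lw = _log_interval_mass(lo - loc, hi - loc) if feas else -np.inf
        segments.append(RaySegment(lo, hi, sig, feas, lw))
    return segments


def _log_interval_mass(a: float, b: float) -> float:
    """log(Phi(b) - Phi(a)) for a standard normal, stable in both tails."""
    if a >= b:
        return -np.inf
    if a > 0:  # reflect to the left tail
        a, b = -b, -a
    la, lb = special.log_ndtr(a), special.log_ndtr(b)
    # lb >= la; log(e^lb - e^la)
    with np.errstate(divide="ignore"):
        return float(lb + np.log1p(-np.exp(min(la - lb, 0.0))))


def sample_step(
    space: ThermoSpace,
    cache: OrthantCache,
    m0: np.ndarray,
    rng: np.random.Generator,
    direction_scales: np.ndarray | None = None,
    fixed_signs: np.ndarray | None = None,
) -> tuple[np.ndarray, Signature, int]:
    """One Hit-and-Run move; returns (next point, its orthant, #orthants on ray)."""
    z = rng.standard_normal(space.q_r)
    if direction_scales is not None:
        z = z * direction_scales
    u = z / np.linalg.norm(z)
    segments = intersect_ray(space, cache, m0, u, fixed_signs)
    n_orthants = len({s.signature for s in segments})
    lws = np.array([s.log_weight for s in segments])
    if np.all(np.isneginf(lws)):
        # numerically degenerate ray: stay put (current segment guarantees
        # aperiodicity; its weight can underflow only at the boundary)
        cur_sig = _signature_at(space.mu_r + space.Q_r @ m0)
        return m0, cur_sig, n_orthants
    probs = np.exp(lws - special.logsumexp(lws))
    probs = probs / probs.sum()
    idx = int(rng.choice(len(segments), p=probs))
    seg = segments[idx]
    loc = -float(m0 @ u)
    s = float(
        truncnorm.ppf(rng.uniform(), seg.a - loc, seg.b - loc, loc=loc)
    )
    if not np.isfinite(s):  # extreme tail fallback: midpoint of segment
        s = 0.5 * (seg.a + seg.b)
    m1 = m0 + s * u
    return m1, seg.signature, n_orthants


@dataclass
class SampleSet:
    """Chains of reduced-coordinate and reaction-energy samples."""

    m_chains: list[np.ndarray]  # each (n_retained, q_r)
    dg_chains: list[np.ndarray]  # each (n_retained, gamma)
    orthant_counts: Counter  # pooled, post burn-in
    chain_orthant_counts: list[Counter]
    n_steps: int
    n_burn: int
    max_ray_orthants: int
    #: per-chain post-burn-in orthant visit sequence (signatures)
    orthant_series: list[list[Signature]] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)
    ln_c: np.ndarray | None = None
    dg0: np.ndarray | None = None

    @property
    def dg_samples(self) -> np.ndarray:
        return np.concatenate(self.dg_chains, axis=0)

    def orthant_table(self) -> pd.DataFrame:
        """Visit-frequency estimates of orthant probabilities.

        The standard error per orthant is the MCMC standard error of the
        visit indicator, computed from its autocorrelation-aware effective
        sample size across chains.  Because visits to rare orthants arrive
        in a small number of correlated excursions, the ESS-based estimate
        is floored by a regenerative (excursion-level) estimate
        ``p * sqrt(2 / n_excursions)``, whose effective event count is the
        number of entries into the orthant.
        """
        total = sum(self.orthant_counts.values())
        per_chain_totals = [
            max(sum(c.values()), 1) for c in self.chain_orthant_counts
        ]
        series = None
        if self.orthant_series:
            length = min(len(s) for s in self.orthant_series)
            series = [s[:length] for s in self.orthant_series]
        rows = []
        for sig, cnt in self.orthant_counts.most_common():
            p = cnt / total
            p_chains = np.array(
                [
                    c.get(sig, 0) / t
                    for c, t in zip(self.chain_orthant_counts, per_chain_totals)
                ]
            )
            se_between = (
                float(np.std(p_chains, ddof=1) / np.sqrt(len(p_chains)))
                if len(p_chains) > 1
                else np.nan
            )
            se = se_between
            if series is not None:
                ind = np.array(
                    [[1.0 if s == sig else 0.0 for s in chain] for chain in series]
                )
                n_eff = diag.ess(ind)[0]
                if np.isfinite(n_eff) and n_eff > 1:
                    se = float(np.sqrt(p * (1 - p) / n_eff))
                # excursion-level floor for clumped rare-orthant visits
                entries = int(
                    sum(
                        np.count_nonzero(np.diff(row, prepend=0.0) > 0)
                        for row in ind
                    )
                )
                se_exc = p * np.sqrt(2.0 / max(entries, 1))
                se = max(se if np.isfinite(se) else 0.0, se_exc)
            if not np.isfinite(se) or se == 0.0:
                se = float(np.sqrt(p * (1 - p) / total))
            rows.append(
                {"signature": sig, "count": cnt, "probability": p, "se": se}
            )
        return pd.DataFrame(rows)

    def to_frame(self, network: MetabolicNetwork) -> pd.DataFrame:
        cols = [f"dg_{network.reaction_ids[j]}" for j in network.gamma]
        frames = []
        for c, dg in enumerate(self.dg_chains):
            df = pd.DataFrame(dg, columns=cols)
            df.insert(0, "chain", c)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def adapt_parametrization(
    space: ThermoSpace,
    pilot_psrf: np.ndarray,
    threshold: float = 1.1,
) -> np.ndarray:
    """Ray-direction scales from a pilot run's per-dimension PSRF.

    Dimensions mixing poorly (PSRF above threshold) get their ray
    components inflated proportionally to PSRF^2; others stay at 1.  Only
    the proposal distribution changes — each move still samples the exact
    conditional along its ray, so the stationary distribution is
    untouched.
    """
    psrf = np.nan_to_num(np.asarray(pilot_psrf, dtype=float), nan=1.0)
    scales = np.ones(space.q_r)
    hot = psrf > threshold
    scales[hot] = psrf[hot] ** 2
    return scales


def run_tfs(
    network: MetabolicNetwork,
    space: ThermoSpace,
    n_steps: int = 5000,
    n_chains: int = 4,
    seed: int = 0,
    burn_in: float = 0.2,
    n_retain: int | None = None,
    v_min: float = DEFAULT_V_MIN,
    adapt: bool = False,
    pilot_fraction: float = 0.1,
    initial_points=None,
    sample_conditionals: bool = False,
) -> SampleSet:
    """Sample the steady-state thermodynamic space.

    Chains start from the over-dispersed interior points found by PMO
    (cycled when there are fewer distinct orthants than chains).  With
    ``adapt=True`` a short pilot run tunes the ray-direction scales first.
    Deterministic given ``seed`` and the configuration.
    """
    if n_chains < 2:
        raise ValueError("at least 2 chains are required for diagnostics")
    if initial_points is None:
        initial_points = find_initial_points(network, space, v_min=v_min)
    cache = OrthantCache(network, v_min)
    fixed = _fixed_direction_signs(network, v_min)
    starts = [initial_points[c % len(initial_points)].m_r for c in range(n_chains)]

    scales = None
    if adapt:
        n_pilot = max(50, int(n_steps * pilot_fraction))
        pilot = _run_chains(
            space, cache, starts, n_pilot, seed_root=(seed, 0xA11), fixed=fixed,
            burn_in=burn_in, n_retain=None, scales=None,
        )
        psrf_m = diag.psrf(
            np.stack([c["m"] for c in pilot]), rank_normalized=True
        )
        scales = adapt_parametrization(space, psrf_m)

    chains = _run_chains(
        space, cache, starts, n_steps, seed_root=(seed, 1), fixed=fixed,
        burn_in=burn_in, n_retain=n_retain, scales=scales,
    )

    m_chains = [c["m"] for c in chains]
    dg_chains = [m @ space.Q_r.T + space.mu_r for m in m_chains]
    pooled: Counter = Counter()
    per_chain = []
    series = []
    for c in chains:
        pooled.update(c["orthants"])
        per_chain.append(c["orthants"])
        series.append(c["series"])
    stagnant = all(len(c["orthants"]) == 1 for c in chains) and len(pooled) == 1
    dgs = np.stack(dg_chains)
    diagnostics = {
        "psrf": diag.psrf(dgs),
        "ess": diag.ess(dgs),
        "n_orthants_discovered": len(pooled),
        "n_lp_calls_cached": len(cache),
        "stagnation": stagnant,
    }
    result = SampleSet(
        m_chains=m_chains,
        dg_chains=dg_chains,
        orthant_counts=pooled,
        chain_orthant_counts=per_chain,
        n_steps=n_steps,
        n_burn=int(n_steps * burn_in),
        max_ray_orthants=max(c["max_ray_orthants"] for c in chains),
        orthant_series=series,
        diagnostics=diagnostics,
    )
    if sample_conditionals:
        rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC0)))
        result.ln_c, result.dg0 = sample_concentrations(
            space, result.dg_samples, rng
        )
    return result


def _run_chains(space, cache, starts, n_steps, seed_root, fixed, burn_in,
                n_retain, scales):
    n_burn = int(n_steps * burn_in)
    keep = n_steps - n_burn
    if n_retain is None or n_retain >= keep:
        retain_idx = np.arange(n_burn, n_steps)
    else:
        retain_idx = n_burn + np.unique(
            np.linspace(0, keep - 1, n_retain).astype(int)
        )
    retain_set = set(int(i) for i in retain_idx)
    out = []
    for c, m0 in enumerate(starts):
        rng = np.random.default_rng(np.random.SeedSequence((*seed_root, c)))
        m = np.array(m0, dtype=float)
        kept = []
        orthants: Counter = Counter()
        series: list = []
        max_cross = 0
        for step in range(n_steps):
            m, sig, n_orth = sample_step(
                space, cache, m, rng, direction_scales=scales,
                fixed_signs=fixed,
            )
            max_cross = max(max_cross, n_orth)
            if step >= n_burn:
                orthants[sig] += 1
                series.append(sig)
            if step in retain_set:
                kept.append(m.copy())
        out.append(
            {
                "m": np.array(kept),
                "orthants": orthants,
                "series": series,
                "max_ray_orthants": max_cross,
            }
        )
    return out


def sample_concentrations(
    space: ThermoSpace,
    dg_samples: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Conditional concentrations and standard energies for energy samples.

    The conditional of ``[ln c, dgr0]`` given the reaction energies is
    Gaussian with a mean linear in the energies and a covariance that does
    not depend on them, so one factorization serves all draws.  The
    standard energies are then reconstructed through the exact energy
    decomposition, which the conditional satisfies almost surely, so every
    returned triple obeys it to machine precision.
    """
    dg_samples = np.atleast_2d(np.asarray(dg_samples, dtype=float))
    cond = space.condition_on_dg(space.mu_r)  # mean at mu_r = prior mean
    B = space._cross_cov()
    K = B @ space._Sigma_r_pinv()
    mu_prior = np.concatenate([space.priors.mu_c, space.priors.mu_0])
    means = mu_prior[None, :] + (dg_samples - space.mu_r[None, :]) @ K.T
    z = rng.standard_normal((len(dg_samples), cond.rank))
    draws = means + z @ cond.Q.T
    ln_c = draws[:, : space.n_mets]
    RT = space.priors.RT
    dg0 = dg_samples - RT * (ln_c @ space.network.S_gamma)
    return ln_c, dg0
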
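"""Most-probable-state optimization: closed forms, oracle equivalence,
monotonicity, initial points, z-scores and anomaly classification."""

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize

from pta.fixtures import FixtureSpec, make_network
from pta.pmo import (
    classify_anomalies,
    find_initial_points,
    solve_pmo,
    z_scores,
)
from pta.tfs import OrthantCache
from pta.thermo import build_joint

from conftest import random_fixture
from test_thermo_space import single_reaction

EPS = 0.1


def oracle_pmo(net, space, epsilon=EPS, v_min=1e-6, reduced=False):
    """Independent oracle: exhaustive orthant enumeration + SLSQP QP.

    Enumerates every direction assignment, keeps those with a steady-state
    flux distribution, solves the convex minimum-norm problem per orthant
    with a different QP code path, and returns the overall minimum.
    """
    gamma = net.n_gamma
    if reduced:
        W, chi2 = space.Q_r, space.chi2_r
    else:
        W, chi2 = space.Q[space.n_mets + gamma :, :], space.chi2
    mu = space.mu_r
    cache = OrthantCache(net, v_min)
    best = np.inf
    fixed = [0] * gamma
    for k, j in enumerate(net.gamma):
        if net.lb[j] >= 0:
            fixed[k] = 1
        elif net.ub[j] <= 0:
            fixed[k] = -1
    for signs in itertools.product((1, -1), repeat=gamma):
        if any(f and f != s for f, s in zip(fixed, signs)):
            continue
        if not cache.feasible(signs):
            continue
        s = np.array(signs, dtype=float)
        A = s[:, None] * W
        b = -epsilon - s * mu
        cons = [{"type": "ineq", "fun": lambda m, A=A, b=b: b - A @ m,
                 "jac": lambda m, A=A: -A}]
        x0 = np.zeros(W.shape[1])
        res = minimize(
            lambda m: m @ m, x0, jac=lambda m: 2 * m, constraints=cons,
            method="SLSQP", options={"maxiter": 500, "ftol": 1e-14},
        )
        if res.success and np.all(A @ res.x <= b + 1e-7):
            obj = float(res.x @ res.x)
            if obj <= chi2 + 1e-9:
                best = min(best, obj)
    return best


class TestClosedForms:
    def test_mean_already_feasible(self):
        # favorable mean energy, wide bounds: the mode is the prior mean
        net, priors = single_reaction(mu_0=-8.0)
        space = build_joint(net, priors)
        res = solve_pmo(net, space)
        assert res.status == "optimal"
        assert res.objective == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.t_star, space.mu_t, atol=1e-9)

    def test_forced_forward_hits_boundary(self):
        # positive mean energy but irreversible forward flux: the energy
        # must be pushed to -epsilon, costing ((mu + eps) / sd)^2
        sd_0 = 3.0
        mu_0 = 4.0
        net, priors = single_reaction(sd_c=0.0, sd_0=sd_0, mu_0=mu_0, lb=0.0)
        space = build_joint(net, priors)
        res = solve_pmo(net, space, epsilon=EPS)
        assert res.status == "optimal"
        assert res.objective == pytest.approx(((mu_0 + EPS) / sd_0) ** 2, rel=1e-8)
        dg_star = space.split_t(res.t_star)[2]
        assert dg_star[0] == pytest.approx(-EPS, abs=1e-8)

    def test_infeasible_when_out_of_confidence(self):
        # forward-forced reaction whose energy cannot reach negative values
        net, priors = single_reaction(sd_c=0.0, sd_0=0.5, mu_0=25.0, lb=0.0)
        space = build_joint(net, priors)
        res = solve_pmo(net, space)
        assert res.status == "infeasible"


class TestOracleEquivalence:
    @pytest.mark.parametrize(
        "fixture",
        [
            ("triangle", dict(dg0_rank_deficient=True, seed=0)),
            ("triangle", dict(seed=1)),
            ("branch", dict(seed=2)),
            ("chain", dict(n_reactions=3, seed=3)),
            ("random", dict(n_reactions=6, seed=4)),
            ("random", dict(n_reactions=8, seed=5)),
        ],
        ids=lambda f: f"{f[0]}-{f[1].get('seed')}",
    )
    def test_matches_exhaustive_enumeration(self, fixture):
        topo, kw = fixture
        net, priors = make_network(FixtureSpec(topology=topo, **kw))
        space = build_joint(net, priors)
        res = solve_pmo(net, space, epsilon=EPS)
        best = oracle_pmo(net, space, epsilon=EPS)
        if res.status == "infeasible":
            assert np.isinf(best)
        else:
            assert res.objective == pytest.approx(best, abs=1e-6)

    def test_solution_satisfies_all_constraints(self, triangle):
        net, priors, space = triangle
        res = solve_pmo(net, space, epsilon=EPS)
        assert res.status == "optimal"
        # steady state of the flux witness
        np.testing.assert_allclose(net.S @ res.v_star, 0.0, atol=1e-8)
        # second law with margin, against the signature
        dg = space.split_t(res.t_star)[2]
        for k in range(net.n_gamma):
            assert res.signature[k] * dg[k] <= -EPS + 1e-8
            assert res.signature[k] * res.v_star[net.gamma[k]] >= 1e-6 - 1e-12
        # confidence ellipsoid
        assert res.objective <= space.chi2 + 1e-9


class TestMonotonicity:
    def test_constraints_never_reduce_objective(self, triangle):
        net, priors, space = triangle
        free = solve_pmo(net, space, epsilon=EPS)
        for sig in itertools.product((1, -1), repeat=2):
            cons = {"R1": sig[0], "R2": sig[1]}
            fixed = solve_pmo(net, space, direction_constraints=cons, epsilon=EPS)
            if fixed.status == "optimal":
                assert fixed.objective >= free.objective - 1e-9

    def test_concentration_constraint_increases_objective(self, chain1):
        net, priors, space = chain1
        free = solve_pmo(net, space)
        pinned = solve_pmo(
            net, space, flux_constraints={"R1": (0.5, 10.0)}
        )
        assert pinned.status == "optimal"
        assert pinned.objective >= free.objective - 1e-12


class TestInitialPoints:
    def test_one_reversible_reaction_two_starts(self, chain1):
        net, priors, space = chain1
        pts = find_initial_points(net, space)
        assert 1 <= len(pts) <= 2
        sigs = {p.signature for p in pts}
        assert len(sigs) == len(pts)

    def test_all_irreversible_single_start(self):
        net, priors = make_network(
            FixtureSpec(topology="chain", n_reactions=2, reversible=False, seed=0)
        )
        space = build_joint(net, priors)
        pts = find_initial_points(net, space)
        assert len(pts) == 1
        assert pts[0].signature == (1, 1)

    def test_points_strictly_interior_and_feasible(self, triangle):
        net, priors, space = triangle
        cache = OrthantCache(net)
        for p in find_initial_points(net, space):
            assert p.m_r @ p.m_r < space.chi2_r - 1e-6
            dg = space.mu_r + space.Q_r @ p.m_r
            assert all(
                s * g < 0 for s, g in zip(p.signature, dg)
            )
            assert cache.feasible(p.signature)

    def test_infeasible_model_reports_structural_cause(self):
        net, priors = make_network(FixtureSpec(topology="forced_cycle"))
        space = build_joint(net, priors)
        with pytest.raises(RuntimeError, match="structural"):
            find_initial_points(net, space)


class TestZScoresAndAnomalies:
    def test_zero_at_mean_and_scaling(self, triangle):
        net, priors, space = triangle
        z = z_scores(space.mu_t, space)
        np.testing.assert_allclose(z, 0.0, atol=1e-12)
        t = space.mu_t.copy()
        t[0] += 2.0 * np.sqrt(space.Sigma_t[0, 0])
        assert z_scores(t, space)[0] == pytest.approx(2.0)

    def test_threshold_rule(self, triangle):
        net, _, _ = triangle
        z = np.array([0.5, 1.2, 0.0])
        c = np.full(3, 1e-4)
        out = classify_anomalies(z, c, net, theta=1.0)
        assert [a.metabolite_id for a in out] == [net.metabolite_ids[1]]

    def test_extracellular_concentration_rule(self, triangle):
        net, _, _ = triangle
        net = net.copy()
        net.compartments[2] = "p"  # periplasmic
        z = np.zeros(3)
        c = np.array([1e-4, 1e-4, 0.012])  # 12 mM
        out = classify_anomalies(z, c, net, theta=1.0)
        assert [a.metabolite_id for a in out] == [net.metabolite_ids[2]]
        assert out[0].reason == "extracellular concentration"

    def test_no_flags_under_loose_threshold(self, triangle):
        net, _, _ = triangle
        out = classify_anomalies(np.ones(3), np.full(3, 1e-4), net, theta=1e9)
        assert out == []


def test_high_z_intermediate_flagged():
    """A squeezed pathway intermediate produces a |z| > 1 anomaly.

    Two-step pathway where the first step is unfavorable and the second
    favorable: feasibility forces the intermediate's concentration far
    below its prior mean, the signature of substrate channeling.
    """
    from pta.network import MetabolicNetwork, ThermoPriors

    net = MetabolicNetwork(
        S=np.array(
            [
                [-1.0, 0.0, 1.0, 0.0],
                [1.0, -1.0, 0.0, 0.0],
                [0.0, 1.0, 0.0, -1.0],
            ]
        ),
        lb=np.array([0.0, 0.0, -10.0, -10.0]),
        ub=np.array([10.0, 10.0, 10.0, 10.0]),
        reaction_ids=["StepA", "StepB", "EX_S", "EX_P"],
        metabolite_ids=["S", "I", "P"],
    )
    net.gamma = [0, 1]
    priors = ThermoPriors(
        mu_c=np.full(3, np.log(1e-4)),
        Sigma_c=np.eye(3) * 1.0,
        # StepA unfavorable at standard conditions, StepB favorable
        mu_0=np.array([8.0, -6.0]),
        Sigma_0=np.eye(2) * 1.0,
    )
    space = build_joint(net, priors)
    res = solve_pmo(net, space)
    assert res.status == "optimal"
    z_mets = res.z[:3]
    ln_c = space.split_t(res.t_star)[0]
    anomalies = classify_anomalies(z_mets, np.exp(ln_c), net, theta=1.0)
    flagged = {a.metabolite_id for a in anomalies}
    assert "I" in flagged
    assert z_mets[1] < -1.0  # intermediate pushed low
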
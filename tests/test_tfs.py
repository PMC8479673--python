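"""Hit-and-Run sampler: ray geometry, step distribution, stationary
distribution against the rejection oracle, adaptation invariance,
conditional concentration sampling, determinism."""

import numpy as np
import pytest
from scipy import stats

from pta.fixtures import FixtureSpec, make_network, rejection_oracle
from pta.pmo import find_initial_points
from pta.tfs import (
    OrthantCache,
    _log_interval_mass,
    adapt_parametrization,
    intersect_ray,
    run_tfs,
    sample_concentrations,
    sample_step,
    steady_state_feasible,
)
from pta.thermo import build_joint

from conftest import random_fixture


class TestOrthantFeasibility:
    def test_flux_coupled_chain_signs(self, triangle):
        net, _, _ = triangle
        # v1 = v2 at steady state: mixed signs on the pathway are impossible
        assert steady_state_feasible(net, (1, 1, 1))
        assert steady_state_feasible(net, (1, 1, -1))
        assert not steady_state_feasible(net, (1, -1, 1))
        assert not steady_state_feasible(net, (-1, 1, 1))

    def test_irreversible_precheck_skips_lp(self):
        net, _ = make_network(
            FixtureSpec(topology="chain", n_reactions=2, reversible=False, seed=0)
        )
        cache = OrthantCache(net)
        assert not steady_state_feasible(net, (-1, 1), cache=cache)
        assert len(cache) == 0  # rejected before any LP

    def test_cache_hits(self, triangle):
        net, _, _ = triangle
        cache = OrthantCache(net)
        assert cache.feasible((1, 1, 1))
        assert cache.feasible((1, 1, 1))
        assert len(cache) == 1


class TestRayIntersection:
    def test_one_dimensional_chord_has_at_most_two_segments(self, chain1):
        net, _, space = chain1
        cache = OrthantCache(net)
        rng = np.random.default_rng(0)
        for _ in range(50):
            m0 = rng.normal(size=space.q_r) * 0.3
            segs = intersect_ray(space, cache, m0, rng.normal(size=space.q_r))
            assert 1 <= len(segs) <= 2
            # segments tile the chord in order
            for s1, s2 in zip(segs[:-1], segs[1:]):
                assert s1.b == pytest.approx(s2.a)

    def test_current_point_in_feasible_segment(self, triangle):
        net, _, space = triangle
        cache = OrthantCache(net)
        rng = np.random.default_rng(1)
        pts = find_initial_points(net, space)
        m0 = pts[0].m_r
        for _ in range(20):
            segs = intersect_ray(space, cache, m0, rng.normal(size=space.q_r))
            holding = [s for s in segs if s.a - 1e-12 <= 0 <= s.b + 1e-12]
            assert holding and holding[0].feasible

    @pytest.mark.parametrize("seed", [0, 1])
    def test_segments_match_dense_scan(self, seed):
        """Orthants along each ray agree with a dense grid evaluation."""
        net, priors, space = random_fixture(seed, n_reactions=6)
        cache = OrthantCache(net)
        rng = np.random.default_rng(seed)
        start = find_initial_points(net, space)[0].m_r
        for _ in range(60):
            u = rng.normal(size=space.q_r)
            u /= np.linalg.norm(u)
            segs = intersect_ray(space, cache, start, u)
            grid = np.linspace(segs[0].a, segs[-1].b, 2000)[1:-1]
            dg = space.mu_r[None, :] + (start[None, :] + grid[:, None] * u) @ space.Q_r.T
            sigs_grid = {
                tuple(1 if g < 0 else -1 for g in row) for row in dg
            }
            sigs_segs = {s.signature for s in segs}
            assert sigs_grid <= sigs_segs
            # every reported segment of nonzero width appears in the scan
            wide = {
                s.signature for s in segs if s.b - s.a > (segs[-1].b - segs[0].a) / 500
            }
            assert wide <= sigs_grid


class TestStepDistribution:
    def test_single_orthant_step_is_truncated_normal(self, chain1):
        """With every orthant feasible, the chain's stationary law is the
        ball-truncated standard normal (KS test)."""
        net, priors, space = chain1
        assert space.q_r == 1
        cache = OrthantCache(net)
        # both directions feasible on an open reversible chain
        assert cache.feasible((1,)) and cache.feasible((-1,))
        rng = np.random.default_rng(7)
        m = np.zeros(1)
        draws = []
        for _ in range(4000):
            m, _, _ = sample_step(space, cache, m, rng)
            draws.append(m[0])
        r = np.sqrt(space.chi2_r)
        ks = stats.kstest(np.array(draws[200:]), stats.truncnorm(-r, r).cdf)
        assert ks.pvalue > 1e-3

    def test_symmetric_segments_balanced(self, chain1):
        net, priors, space = chain1
        cache = OrthantCache(net)
        rng = np.random.default_rng(3)
        m = np.zeros(1)
        signs = []
        for _ in range(4000):
            m, sig, _ = sample_step(space, cache, m, rng)
            signs.append(sig[0])
        # the energy prior is asymmetric, but crossing both orthants must
        # happen: each visited in nontrivial proportion
        frac = np.mean(np.array(signs) == 1)
        assert 0.01 < frac < 0.99

    def test_far_tail_masses_finite(self):
        assert np.isfinite(_log_interval_mass(8.2, 9.0))
        assert np.isfinite(_log_interval_mass(-9.0, -8.2))
        assert _log_interval_mass(8.2, 9.0) == pytest.approx(
            _log_interval_mass(-9.0, -8.2)
        )
        assert _log_interval_mass(1.0, 1.0) == -np.inf


class TestStationaryDistribution:
    def test_orthant_probabilities_match_rejection_oracle(self, triangle):
        net, priors, space = triangle
        oracle = rejection_oracle(
            net, space, n_draws=300_000, rng=np.random.default_rng(11)
        )
        result = run_tfs(net, space, n_steps=4000, n_chains=4, seed=5)
        table = result.orthant_table()
        for _, row in table.iterrows():
            p_true = oracle.probability(row["signature"])
            se = np.sqrt(row["se"] ** 2 + p_true * (1 - p_true) / len(oracle.dg_samples))
            assert abs(row["probability"] - p_true) < 3 * max(se, 1e-4)

    def test_one_dim_closed_form_split(self, chain1):
        """Single-reaction orthant split equals the truncated-normal mass."""
        net, priors, space = chain1
        result = run_tfs(net, space, n_steps=6000, n_chains=4, seed=2)
        table = result.orthant_table().set_index("signature")
        r = np.sqrt(space.chi2_r)
        # dg < 0 <=> m < -mu_r / sd_r for the scalar reduced space
        cut = -space.mu_r[0] / space.Q_r[0, 0]
        tn = stats.truncnorm(-r, r)
        p_fwd = tn.cdf(np.clip(cut, -r, r))
        got = table.loc[[(1,)], "probability"].iloc[0] if (1,) in table.index else 0.0
        se = table["se"].max()
        assert got == pytest.approx(p_fwd, abs=max(3 * se, 0.02))

    def test_every_sample_in_the_space(self, triangle):
        net, priors, space = triangle
        result = run_tfs(net, space, n_steps=1500, n_chains=2, seed=9)
        cache = OrthantCache(net)
        for m_chain, dg_chain in zip(result.m_chains, result.dg_chains):
            norms = np.einsum("ij,ij->i", m_chain, m_chain)
            assert np.all(norms <= space.chi2_r + 1e-9)
            for dg in dg_chain:
                sig = tuple(1 if g < 0 else -1 for g in dg)
                assert cache.feasible(sig)

    def test_ray_crossing_bound(self):
        """A ray never crosses more than gamma+1 orthants; with full-rank
        priors the reduced dimension equals gamma and the bound is q_r+1."""
        for seed in (0, 1):
            net, priors, space = random_fixture(seed, n_reactions=5)
            assert space.q_r == net.n_gamma  # full-rank fixture
            result = run_tfs(net, space, n_steps=1500, n_chains=2, seed=seed)
            assert result.max_ray_orthants <= space.q_r + 1

    def test_rank_deficient_bound_is_ambient(self, triangle):
        net, priors, space = triangle
        result = run_tfs(net, space, n_steps=1500, n_chains=2, seed=4)
        assert result.max_ray_orthants <= net.n_gamma + 1


class TestAdaptation:
    def test_unit_psrf_no_rescaling(self, triangle):
        _, _, space = triangle
        scales = adapt_parametrization(space, np.ones(space.q_r))
        np.testing.assert_array_equal(scales, 1.0)

    def test_only_hot_dimension_rescaled(self, triangle):
        _, _, space = triangle
        psrf = np.ones(space.q_r)
        psrf[1] = 1.5
        scales = adapt_parametrization(space, psrf)
        assert scales[1] == pytest.approx(1.5**2)
        assert scales[0] == 1.0

    def test_adaptation_preserves_stationary_marginals(self, triangle):
        net, priors, space = triangle
        plain = run_tfs(net, space, n_steps=6000, n_chains=4, seed=21)
        adapted = run_tfs(net, space, n_steps=6000, n_chains=4, seed=22, adapt=True)
        for d in range(net.n_gamma):
            a = plain.dg_samples[:, d]
            b = adapted.dg_samples[:, d]
            # two-sample KS on thinned draws (loose: MCMC autocorrelation)
            ks = stats.ks_2samp(a[::20], b[::20])
            assert ks.pvalue > 1e-4


class TestConditionals:
    def test_identity_holds_to_machine_precision(self, triangle, rng):
        net, priors, space = triangle
        result = run_tfs(net, space, n_steps=1000, n_chains=2, seed=3)
        ln_c, dg0 = sample_concentrations(space, result.dg_samples, rng)
        resid = result.dg_samples - dg0 - priors.RT * (ln_c @ net.S_gamma)
        assert np.abs(resid).max() < 1e-8

    def test_degenerate_energy_prior(self):
        from test_thermo_space import single_reaction

        net, priors = single_reaction(sd_0=0.0)
        space = build_joint(net, priors)
        rng = np.random.default_rng(0)
        dg = space.mu_r[None, :] + rng.normal(size=(200, 1)) @ space.Q_r.T
        ln_c, dg0 = sample_concentrations(space, dg, rng)
        np.testing.assert_allclose(dg0, priors.mu_0[0], atol=1e-6)
        np.testing.assert_allclose(
            priors.RT * (ln_c @ net.S_gamma), dg - priors.mu_0[0], atol=1e-6
        )

    def test_mean_energy_gives_prior_mean(self, chain2, rng):
        net, priors, space = chain2
        dg = np.tile(space.mu_r, (20_000, 1))
        ln_c, dg0 = sample_concentrations(space, dg, rng)
        se = ln_c.std(axis=0).max() / np.sqrt(len(ln_c))
        np.testing.assert_allclose(
            ln_c.mean(axis=0), priors.mu_c, atol=4 * se + 1e-9
        )


class TestDeterminism:
    def test_identical_seeds_identical_streams(self, triangle):
        net, priors, space = triangle
        a = run_tfs(net, space, n_steps=800, n_chains=2, seed=13,
                    sample_conditionals=True)
        b = run_tfs(net, space, n_steps=800, n_chains=2, seed=13,
                    sample_conditionals=True)
        for ca, cb in zip(a.m_chains, b.m_chains):
            np.testing.assert_array_equal(ca, cb)
        assert a.orthant_counts == b.orthant_counts
        np.testing.assert_array_equal(a.ln_c, b.ln_c)

    def test_different_seeds_differ(self, triangle):
        net, priors, space = triangle
        a = run_tfs(net, space, n_steps=500, n_chains=2, seed=1)
        b = run_tfs(net, space, n_steps=500, n_chains=2, seed=2)
        assert not np.array_equal(a.m_chains[0], b.m_chains[0])


def test_chains_from_different_orthants_converge(triangle):
    net, priors, space = triangle
    result = run_tfs(net, space, n_steps=8000, n_chains=4, seed=17)
    starts = {p.signature for p in find_initial_points(net, space)}
    assert len(starts) >= 2  # genuinely over-dispersed starts
    assert np.all(result.diagnostics["psrf"] < 1.05)
    assert np.all(np.nan_to_num(result.diagnostics["ess"], nan=1e9) > 100)
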
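import dataclasses

import numpy as np
import pytest

from hmtree.inference import (
    EmConfig,
    _fit_alt_block,
    e_step,
    fit_em,
    m_step,
    marginal_state_probs,
    posterior_beliefs,
    upward_pass,
)
from hmtree.model import HmtmParams, null_density, alt_density
from hmtree.synthetic import (
    SimConfig,
    brute_force_likelihood,
    brute_force_posteriors,
    simulate_dataset,
)

from conftest import make_tree, random_instance

THETA = HmtmParams(0.9, 0.7, 0.3, 10.0, 1.0, 2.0, 2.0)


class TestMarginals:
    def test_depth_decay(self):
        tree = make_tree([-1, 0, 1])  # a chain
        prior = marginal_state_probs(tree, 0.9, 0.5)
        assert prior[:, 1] == pytest.approx([0.9, 0.45, 0.225])
        assert np.allclose(prior.sum(axis=1), 1.0)

    def test_root_prior_is_pi(self):
        tree = make_tree([-1, 0, 0])
        assert marginal_state_probs(tree, 0.42, 0.7)[0, 1] == 0.42

    def test_persistence_limit(self):
        tree = make_tree([-1, 0, 1, 2, 3])
        prior = marginal_state_probs(tree, 0.8, 1.0 - 1e-9)
        assert np.allclose(prior[:, 1], 0.8, atol=1e-7)


class TestUpwardDownward:
    def test_single_node_closed_form(self):
        tree = make_tree([-1])
        p = np.array([0.03])
        beliefs = upward_pass(tree, p, THETA)
        expected = np.log(
            THETA.pi * alt_density(p[0], THETA.alpha, THETA.beta)
            + (1 - THETA.pi) * null_density(p[0], THETA.lam, THETA.alpha0, THETA.beta0)
        )
        assert beliefs.loglik == pytest.approx(float(expected), abs=1e-12)

    def test_two_node_chain_matches_hand_enumeration(self):
        tree = make_tree([-1, 0])
        p = np.array([0.02, 0.4])
        q = THETA.transition_matrix
        f = lambda x, s: (
            alt_density(x, THETA.alpha, THETA.beta)
            if s
            else null_density(x, THETA.lam, THETA.alpha0, THETA.beta0)
        )
        total = sum(
            (THETA.pi if s1 else 1 - THETA.pi)
            * q[s1, s2]
            * f(p[0], s1)
            * f(p[1], s2)
            for s1 in (0, 1)
            for s2 in (0, 1)
        )
        beliefs = upward_pass(tree, p, THETA)
        assert beliefs.loglik == pytest.approx(float(np.log(total)), abs=1e-12)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_enumeration_oracle(self, seed):
        tree, p, theta = random_instance(np.random.default_rng(seed))
        beliefs = posterior_beliefs(tree, p, theta)
        assert beliefs.loglik == pytest.approx(
            brute_force_likelihood(tree, p, theta), abs=1e-9
        )
        marg, _, _, _ = brute_force_posteriors(tree, p, theta)
        assert np.allclose(beliefs.posterior[:, 1], marg, atol=1e-9)

    def test_tau_and_posterior_normalized(self):
        rng = np.random.default_rng(5)
        tree, p, theta = random_instance(rng, max_nodes=12)
        beliefs = posterior_beliefs(tree, p, theta)
        assert np.allclose(beliefs.tau.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(beliefs.posterior.sum(axis=1), 1.0, atol=1e-10)
        assert beliefs.posterior[0, 1] == pytest.approx(beliefs.tau[0, 1], abs=1e-14)

    def test_scaled_recursions_stay_finite_at_scale(self):
        # deep-and-wide simulated tree; every intermediate must stay finite
        data = simulate_dataset(
            SimConfig(theta=THETA, seed=3, n_dag_nodes=10_000, n_genes=30_000,
                      multi_parent_fraction=0.0, max_children=3)
        )
        assert int(data.tree.depth.max()) >= 14
        beliefs = posterior_beliefs(data.tree, data.pvals, THETA)
        for arr in (beliefs.tau, beliefs.tau_edge, beliefs.kappa, beliefs.posterior):
            assert np.all(np.isfinite(arr))
        assert np.isfinite(beliefs.loglik)


class TestEStep:
    @pytest.mark.parametrize("seed", range(15))
    def test_joint_expectations_match_enumeration(self, seed):
        tree, p, theta = random_instance(np.random.default_rng(100 + seed))
        beliefs = posterior_beliefs(tree, p, theta)
        stats = e_step(tree, beliefs, theta)
        marg, e11, e10, _ = brute_force_posteriors(tree, p, theta)
        assert np.allclose(stats.w, marg, atol=1e-9)
        assert np.allclose(stats.e11[1:], e11[1:], atol=1e-9)
        assert np.allclose(stats.e10[1:], e10[1:], atol=1e-9)

    def test_joints_sum_to_parent_posterior(self):
        rng = np.random.default_rng(8)
        tree, p, theta = random_instance(rng)
        beliefs = posterior_beliefs(tree, p, theta)
        stats = e_step(tree, beliefs, theta)
        for i in range(1, tree.n_nodes):
            parent = tree.parent[i]
            assert stats.e11[i] + stats.e10[i] == pytest.approx(
                stats.w[parent], abs=1e-10
            )

    def test_uninformative_emissions_give_prior(self):
        # lam=1 null is uniform; alpha=1, beta->1 makes the alternative
        # uniform too, so the posterior must collapse onto the prior
        theta = HmtmParams(0.8, 0.6, 1.0, 1.0 + 1e-12, 1.0, 2.0, 2.0)
        tree = make_tree([-1, 0, 0, 1, 1, 2])
        p = np.random.default_rng(1).uniform(0.05, 0.95, tree.n_nodes)
        beliefs = posterior_beliefs(tree, p, theta)
        prior = marginal_state_probs(tree, theta.pi, theta.omega)
        assert np.allclose(beliefs.posterior[:, 1], prior[:, 1], atol=1e-9)


class TestMStep:
    def _stats(self, tree, p, theta):
        return e_step(tree, posterior_beliefs(tree, p, theta), theta)

    def test_pi_update_is_root_posterior(self):
        tree, p, theta = random_instance(np.random.default_rng(2))
        stats = self._stats(tree, p, theta)
        new, _ = m_step(stats, p, theta)
        assert new.pi == pytest.approx(float(np.clip(stats.w[0], 1e-6, 1 - 1e-6)))

    def test_omega_caps_under_degenerate_responsibilities(self):
        tree, p, theta = random_instance(np.random.default_rng(4))
        stats = self._stats(tree, p, theta)
        stats.e11[1:] = 1.0
        stats.e10[1:] = 0.0
        stats = dataclasses.replace(
            stats, p11=float(stats.e11.sum()), p10=0.0
        )
        new, _ = m_step(stats, p, theta)
        assert new.omega == pytest.approx(1.0 - 1e-6)

    def test_weighted_beta_mle_recovers_truth(self):
        # hard 0/1 weights: the alternative block reduces to a plain beta
        # fit on the w=1 subset and must recover the generating shapes
        rng = np.random.default_rng(11)
        a_star, b_star = 0.3, 10.0
        n = 5000
        p_alt = rng.beta(a_star, b_star, size=n)
        p_null = rng.uniform(size=n)
        p = np.concatenate([p_alt, p_null])
        w = np.concatenate([np.ones(n), np.zeros(n)])
        a_hat, b_hat, ok = _fit_alt_block(np.clip(p, 1e-15, 1 - 1e-15), w, 0.5, 5.0)
        assert ok
        assert a_hat == pytest.approx(a_star, abs=0.05)
        assert b_hat == pytest.approx(b_star, abs=0.5)


class TestFitEm:
    def test_deterministic_given_seed(self):
        data = simulate_dataset(
            SimConfig(theta=THETA, seed=21, n_dag_nodes=150, n_genes=450,
                      multi_parent_fraction=0.0)
        )
        cfg = EmConfig(seed=5, n_restarts=2, max_iter=60)
        r1 = fit_em(data.tree, data.pvals, cfg)
        r2 = fit_em(data.tree, data.pvals, cfg)
        assert r1.theta == r2.theta
        assert r1.trace == r2.trace
        assert r1.best_index == r2.best_index

    def test_trace_nondecreasing(self):
        data = simulate_dataset(
            SimConfig(theta=THETA, seed=22, n_dag_nodes=300, n_genes=900,
                      multi_parent_fraction=0.0)
        )
        result = fit_em(data.tree, data.pvals, EmConfig(seed=1, n_restarts=3))
        trace = np.array(result.trace)
        assert np.all(np.diff(trace) >= -1e-8)
        assert result.converged

    def test_recovers_omega_on_simulated_data(self):
        theta_star = HmtmParams(0.95, 0.6, 0.3, 10.0, 1.0, 2.0, 2.0)
        data = simulate_dataset(
            SimConfig(theta=theta_star, seed=1, n_dag_nodes=2000, n_genes=6000,
                      multi_parent_fraction=0.0)
        )
        result = fit_em(data.tree, data.pvals, EmConfig(seed=1, n_restarts=3))
        assert abs(result.theta.omega - 0.6) < 0.1

    def test_flat_likelihood_in_pi_omega_when_emissions_uninformative(self):
        # with both densities uniform the data carry no information about
        # (pi, omega): the likelihood surface must be flat
        tree = make_tree([-1, 0, 0, 1, 2, 2, 3])
        p = np.random.default_rng(9).uniform(0.05, 0.95, tree.n_nodes)
        lls = [
            upward_pass(
                tree, p, HmtmParams(pi, om, 1.0, 1.0 + 1e-12, 1.0, 2.0, 2.0)
            ).loglik
            for pi in (0.2, 0.5, 0.9)
            for om in (0.3, 0.6, 0.95)
        ]
        assert max(lls) - min(lls) < 1e-9
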
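"""Sticky HDP-HMM sampler: path sampling, sticky prior, joint density, recovery."""

import itertools

import numpy as np
import pytest
from scipy import stats

from repeatcn.model import Hyperparams, betabinom_logpmf
from repeatcn.rcn_infer import (
    ChainDraw,
    forward_backward_sample,
    infer_rcn,
    log_joint,
    sticky_row_expectation,
)
from repeatcn.simulate import simulate_bias, simulate_rcn_sample, synthetic_loci


class TestStickyRowExpectation:
    def test_full_stickiness(self):
        row = sticky_row_expectation(np.array([0.3, 0.7]), 1.0, 1)
        np.testing.assert_allclose(row, [0.0, 1.0])

    def test_no_stickiness(self):
        beta = np.array([0.2, 0.5, 0.3])
        np.testing.assert_allclose(sticky_row_expectation(beta, 0.0, 0), beta)

    def test_convex_combination(self):
        row = sticky_row_expectation(np.array([0.5, 0.5]), 0.9, 0)
        np.testing.assert_allclose(row, [0.95, 0.05])

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sticky_row_expectation(np.array([0.5, 0.6]), 0.5, 0)
        with pytest.raises(ValueError):
            sticky_row_expectation(np.array([0.5, 0.5]), 1.5, 0)


class TestForwardBackward:
    def test_single_state(self):
        z = forward_backward_sample(np.zeros((5, 1)), np.ones((1, 1)), np.ones(1), 0)
        assert z.tolist() == [0] * 5

    def test_absorbing_identity_chain(self):
        log_em = np.zeros((6, 2))
        pi = np.eye(2)
        z = forward_backward_sample(log_em, pi, np.array([1.0, 0.0]), 1)
        assert z.tolist() == [0] * 6

    def test_matches_exhaustive_enumeration(self):
        """Sampled path frequencies vs brute-force enumeration of all 8 paths."""
        log_em = np.log(np.array([[0.7, 0.3], [0.2, 0.8], [0.5, 0.5]]))
        pi = np.array([[0.9, 0.1], [0.3, 0.7]])
        pi0 = np.array([0.6, 0.4])
        probs = {}
        for path in itertools.product([0, 1], repeat=3):
            p = pi0[path[0]] * np.exp(log_em[0, path[0]])
            for l in range(1, 3):
                p *= pi[path[l - 1], path[l]] * np.exp(log_em[l, path[l]])
            probs[path] = p
        total = sum(probs.values())
        probs = {k: v / total for k, v in probs.items()}

        rng = np.random.default_rng(17)
        draws = 100_000
        counts = {k: 0 for k in probs}
        for _ in range(draws):
            z = forward_backward_sample(log_em, pi, pi0, rng)
            counts[tuple(z)] += 1
        for path, p in probs.items():
            se = np.sqrt(p * (1 - p) / draws)
            assert abs(counts[path] / draws - p) < 3 * se, path

    def test_all_neg_inf_row_errors(self):
        log_em = np.zeros((3, 2))
        log_em[1] = -np.inf
        with pytest.raises(ValueError):
            forward_backward_sample(log_em, np.full((2, 2), 0.5), np.array([0.5, 0.5]), 0)


class TestStickyPriorConstruction:
    def test_transition_row_moments(self):
        """Dirichlet rows built as apk*((1-rho)beta + rho delta) match the
        stated prior mean and the variance that shrinks as 1/(apk + 1)."""
        beta = np.array([0.15, 0.35, 0.5])
        rho, apk, u = 0.9, 200.0, 1
        alpha_vec = apk * ((1 - rho) * beta + rho * np.eye(3)[u])
        rng = np.random.default_rng(3)
        rows = rng.dirichlet(alpha_vec, size=20_000)
        expect = sticky_row_expectation(beta, rho, u)
        se = rows.std(axis=0) / np.sqrt(len(rows))
        assert np.all(np.abs(rows.mean(axis=0) - expect) < 3 * se)
        var_expect = expect * (1 - expect) / (apk + 1.0)
        m4 = ((rows - rows.mean(0)) ** 4).mean(0)
        se_var = np.sqrt(np.maximum(m4 - rows.var(0) ** 2, 0) / len(rows))
        assert np.all(np.abs(rows.var(axis=0) - var_expect) < 3 * se_var)


class TestLogJoint:
    def _toy(self):
        y = np.array([3, 5, 2, 4])
        m = np.array([0.2, 0.3, 0.1, 0.15])
        arms = ["1p"] * 4
        hp = Hyperparams(rho=(5.0, 2.0), alpha_plus_kappa=(3.0, 10.0))
        draw = ChainDraw(
            z=np.array([0, 1, 1, 0]),
            c=np.array([0.8, 1.6]),
            beta=np.array([0.6, 0.4]),
            pi=np.array([[0.9, 0.1], [0.2, 0.8]]),
            pi0=np.array([0.5, 0.5]),
            s_tilde=50.0,
            rho=0.8,
            alpha_plus_kappa=30.0,
        )
        return y, m, arms, hp, draw

    def test_matches_brute_force_product(self):
        """Independent oracle: chain product, reference pmf and scipy priors."""
        y, m, arms, hp, draw = self._toy()
        n = y.sum()
        z, c = draw.z, draw.c
        oracle = np.log(draw.pi0[z[0]])
        for l in range(1, 4):
            oracle += np.log(draw.pi[z[l - 1], z[l]])
        for l in range(4):
            oracle += betabinom_logpmf(y[l], n, c[z[l]], m[l], draw.s_tilde)
        oracle += stats.gamma.logpdf(c, hp.lam[0], scale=hp.lam[1]).sum()
        oracle += stats.gamma.logpdf(draw.s_tilde, hp.omega[0], scale=hp.omega[1])
        oracle += stats.beta.logpdf(draw.rho, *hp.rho)
        oracle += stats.gamma.logpdf(
            draw.alpha_plus_kappa, hp.alpha_plus_kappa[0], scale=hp.alpha_plus_kappa[1]
        )
        oracle += stats.dirichlet.logpdf(draw.beta, np.full(2, hp.gamma / 2))
        alpha = (1 - draw.rho) * draw.alpha_plus_kappa
        kappa = draw.rho * draw.alpha_plus_kappa
        oracle += stats.dirichlet.logpdf(draw.pi0, alpha * draw.beta)
        for u in range(2):
            a = alpha * draw.beta + kappa * np.eye(2)[u]
            oracle += stats.dirichlet.logpdf(draw.pi[u], a)
        assert log_joint(draw, y, arms, m, hp) == pytest.approx(oracle, abs=1e-8)

    def test_constraint_violation_is_neg_inf(self):
        y, m, arms, hp, draw = self._toy()
        draw.c = np.array([0.8, 20.0])  # c*m > 1 at assigned loci
        assert log_joint(draw, y, arms, m, hp) == -np.inf

    def test_emission_difference_isolates_chain_terms(self):
        # two draws differing only in c: log_joint difference equals the
        # emission + c-prior difference (chain terms cancel)
        y, m, arms, hp, draw = self._toy()
        n = y.sum()
        lj1 = log_joint(draw, y, arms, m, hp)
        draw2 = ChainDraw(**{**draw.__dict__})
        draw2.c = np.array([0.9, 1.4])
        lj2 = log_joint(draw2, y, arms, m, hp)
        diff_oracle = 0.0
        for l in range(4):
            diff_oracle += betabinom_logpmf(y[l], n, draw2.c[draw.z[l]], m[l], draw.s_tilde)
            diff_oracle -= betabinom_logpmf(y[l], n, draw.c[draw.z[l]], m[l], draw.s_tilde)
        diff_oracle += (
            stats.gamma.logpdf(draw2.c, hp.lam[0], scale=hp.lam[1]).sum()
            - stats.gamma.logpdf(draw.c, hp.lam[0], scale=hp.lam[1]).sum()
        )
        assert lj2 - lj1 == pytest.approx(diff_oracle, abs=1e-8)


class TestInferRcn:
    def test_seed_determinism(self):
        loci = synthetic_loci(60, seed=41)
        m = simulate_bias(60, seed=42)
        y, _ = simulate_rcn_sample(m, 1e4, 100_000, [(30, 1.0), (30, 2.0)], seed=43)
        t1 = infer_rcn(y, loci["arm"], m, iters=200, burn=50, thin=1, K_max=8, seed=9)
        t2 = infer_rcn(y, loci["arm"], m, iters=200, burn=50, thin=1, K_max=8, seed=9)
        assert np.array_equal(t1.z, t2.z)
        assert np.array_equal(t1.c, t2.c)
        assert np.array_equal(t1.s_tilde, t2.s_tilde)

    def test_loci_mismatch_errors(self):
        with pytest.raises(ValueError):
            infer_rcn(np.array([1, 2, 3]), ["1p"] * 3, np.array([0.5, 0.5]))

    def test_trace_contract(self, four_state_run):
        tr = four_state_run["trace"]
        assert tr.n_stored == (5000 - 1000) // 5
        assert np.all(tr.populated_counts >= 1)
        assert np.all(tr.c >= 0)
        assert np.all((tr.rho > 0) & (tr.rho < 1))
        # stochastic rows
        np.testing.assert_allclose(tr.pi.sum(axis=2), 1.0, atol=1e-5)
        np.testing.assert_allclose(tr.beta.sum(axis=1), 1.0, atol=1e-9)

    def test_truncation_insensitivity(self):
        """K_max well above the needed state count does not move the posterior."""
        loci = synthetic_loci(200, seed=51)
        m = simulate_bias(200, seed=52)
        y, truth = simulate_rcn_sample(m, 1e4, 500_000, [(100, 1.0), (100, 2.0)], seed=53)
        post = []
        for kmax in (10, 20):
            tr = infer_rcn(y, loci["arm"], m, iters=800, burn=300, thin=1, K_max=kmax, seed=54)
            post.append(tr.locus_rcn_draws().mean(axis=0))
        assert np.allclose(post[0], post[1], atol=0.05)
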
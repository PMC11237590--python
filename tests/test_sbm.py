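import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import oracles
from fermnet import sbm
from fermnet.synthetic import PlantedMultiplexConfig, generate_planted_multiplex


def _random_instance(seed, N=6, L=2, Q=2, with_mask=False):
    rng = np.random.default_rng(seed)
    A = rng.poisson(1.5, size=(L, N, N))
    A = np.triu(A, 1)
    A = A + A.transpose(0, 2, 1)
    tau = rng.dirichlet(np.ones(Q), size=N)
    mask = None
    if with_mask:
        presence = rng.random((L, N)) < 0.8
        presence[:, 0] = True
        mask = (presence[:, :, None] & presence[:, None, :]).astype(float)
        for l in range(L):
            np.fill_diagonal(mask[l], 0.0)
        A = A * mask.astype(np.int64)
    return A, tau, mask


class TestMStep:
    def test_q1_rate_is_mean_offdiagonal(self):
        A, _, _ = _random_instance(0, Q=1)
        tau = np.ones((6, 1))
        _, lam = sbm.vem_m_step(A, tau)
        for l in range(2):
            off = A[l][~np.eye(6, dtype=bool)]
            assert lam[l][0, 0] == pytest.approx(off.mean())

    def test_uniform_tau_gives_uniform_pi(self):
        A, _, _ = _random_instance(1)
        tau = np.full((6, 3), 1 / 3)
        pi, _ = sbm.vem_m_step(A, tau)
        assert np.allclose(pi, 1 / 3)

    def test_hard_tau_recovers_blockwise_means(self):
        A, _, _ = _random_instance(2)
        labels = np.array([0, 0, 0, 1, 1, 1])
        tau = np.zeros((6, 2))
        tau[np.arange(6), labels] = 1.0
        _, lam = sbm.vem_m_step(A, tau)
        blk0 = A[0][np.ix_([0, 1, 2], [0, 1, 2])]
        assert lam[0][0, 0] == pytest.approx(
            blk0[~np.eye(3, dtype=bool)].mean())
        assert lam[0][0, 1] == pytest.approx(A[0][np.ix_([0, 1, 2], [3, 4, 5])].mean())

    @pytest.mark.parametrize("with_mask", [False, True])
    def test_m_step_matches_bruteforce_oracle(self, with_mask):
        for seed in range(5):
            A, tau, mask = _random_instance(seed, with_mask=with_mask)
            pi, lam = sbm.vem_m_step(A, tau, mask)
            pi_o, lam_o = oracles.sbm_m_step(
                A.tolist(), tau.tolist(),
                mask.tolist() if mask is not None else None)
            assert np.allclose(pi, pi_o, atol=1e-10)
            assert np.allclose(lam, np.maximum(lam_o, 1e-10), atol=1e-10)


class TestEStep:
    def test_q1_returns_ones(self):
        A, _, _ = _random_instance(0, Q=1)
        tau = np.ones((6, 1))
        pi, lam = sbm.vem_m_step(A, tau)
        assert np.allclose(sbm.vem_e_step(A, tau, pi, lam), 1.0)

    def test_disconnected_cliques_harden(self):
        N = 10
        A = np.zeros((1, N, N))
        A[0, :5, :5] = 3
        A[0, 5:, 5:] = 3
        A[0, np.arange(N), np.arange(N)] = 0
        # separated initialization: each clique leans toward its own block
        tau = np.full((N, 2), 0.25)
        tau[:5, 0] = 0.75
        tau[5:, 1] = 0.75
        for _ in range(20):
            pi, lam = sbm.vem_m_step(A, tau)
            tau = sbm.vem_e_step(A, tau, pi, lam)
        labels = tau.argmax(1)
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]
        assert tau.max(axis=1).min() > 0.99

    def test_fixed_point_is_stable(self):
        mplex, _ = generate_planted_multiplex(
            PlantedMultiplexConfig(N=30, L=2, Q=2, seed=0))
        model = sbm.MultiplexSBM.from_multiplex(mplex)
        fit = model.fit(Q=2, n_restarts=2, seed=0, tol=1e-12, max_iter=2000)
        again = sbm.vem_e_step(model.A, fit.tau, fit.pi, fit.lam, model.mask)
        assert np.abs(again - fit.tau).max() < 1e-6


class TestElbo:
    def test_matches_enumeration_oracle_on_toy(self):
        for seed in range(3):
            A, tau, _ = _random_instance(seed, N=4, L=2, Q=2)
            pi, lam = sbm.vem_m_step(A, tau)
            ours = sbm.elbo(A, tau, pi, lam)
            # enumeration oracle computes sum_z q(z) [log p(A,z) - log q(z)]
            mask = np.ones((2, 4, 4)) - np.eye(4)
            brute = oracles.poisson_sbm_elbo(
                A.tolist(), tau.tolist(), pi.tolist(), lam.tolist(),
                mask.tolist())
            assert ours == pytest.approx(brute, abs=1e-8)

    def test_invariant_under_block_relabeling(self):
        A, tau, _ = _random_instance(1, Q=3)
        pi, lam = sbm.vem_m_step(A, tau)
        perm = [2, 0, 1]
        assert sbm.elbo(A, tau, pi, lam) == pytest.approx(
            sbm.elbo(A, tau[:, perm], pi[perm],
                     lam[:, perm][:, :, perm]))

    def test_single_node(self):
        A = np.zeros((1, 1, 1))
        tau = np.array([[0.3, 0.7]])
        pi = np.array([0.3, 0.7])
        lam = np.full((1, 2, 2), 1.0)
        expected = -(0.3 * np.log(0.3) + 0.7 * np.log(0.7)) + (
            0.3 * np.log(0.3) + 0.7 * np.log(0.7))
        assert sbm.elbo(A, tau, pi, lam) == pytest.approx(expected)


class TestFit:
    def test_elbo_trace_monotone(self):
        mplex, _ = generate_planted_multiplex(
            PlantedMultiplexConfig(N=40, L=3, Q=2, seed=1))
        fit = sbm.fit_multiplex_sbm(mplex, Q=3, n_restarts=3, seed=1)
        assert np.all(np.diff(fit.elbo_trace) >= -1e-8)

    def test_planted_two_block_recovery(self):
        mplex, labels = generate_planted_multiplex(
            PlantedMultiplexConfig(N=60, L=4, Q=2, lam_in=4.0, lam_out=0.2,
                                   seed=5))
        fit = sbm.fit_multiplex_sbm(mplex, Q=2, n_restarts=5, seed=5)
        assert adjusted_rand_score(labels, fit.labels) >= 0.9

    def test_rate_recovery_without_truncation(self):
        """Median relative error of recovered rates stays within 15%."""
        errs = []
        for seed in range(10):
            cfg = PlantedMultiplexConfig(N=80, L=4, Q=2, lam_in=4.0,
                                         lam_out=0.4, truncate_at=None,
                                         seed=seed)
            mplex, labels = generate_planted_multiplex(cfg)
            fit = sbm.fit_multiplex_sbm(mplex, Q=2, n_restarts=3, seed=seed)
            _, lam_true = cfg.resolved()
            # align estimated blocks to truth by majority vote
            order = []
            for q in range(2):
                members = fit.labels == q
                order.append(np.bincount(labels[members], minlength=2).argmax())
            lam_hat = fit.lam[:, :, order][:, order, :]
            errs.append(np.median(np.abs(lam_hat - lam_true) / lam_true))
        assert np.median(errs) <= 0.15

    def test_q1_closed_form_single_iteration(self):
        mplex, _ = generate_planted_multiplex(
            PlantedMultiplexConfig(N=20, L=2, Q=2, seed=2))
        fit = sbm.fit_multiplex_sbm(mplex, Q=1, seed=0)
        assert fit.n_iter == 1 and fit.converged
        assert fit.tau.shape == (20, 1)

    def test_same_seed_identical_fit(self):
        mplex, _ = generate_planted_multiplex(
            PlantedMultiplexConfig(N=30, L=2, Q=2, seed=3))
        a = sbm.fit_multiplex_sbm(mplex, Q=2, n_restarts=3, seed=7)
        b = sbm.fit_multiplex_sbm(mplex, Q=2, n_restarts=3, seed=7)
        assert np.array_equal(a.tau, b.tau)
        assert a.elbo == b.elbo

    def test_q_exceeding_n_rejected(self):
        mplex, _ = generate_planted_multiplex(
            PlantedMultiplexConfig(N=5, L=1, Q=1, seed=0))
        with pytest.raises(ValueError):
            sbm.fit_multiplex_sbm(mplex, Q=6)

    def test_tau_rows_sum_to_one(self):
        mplex, _ = generate_planted_multiplex(
            PlantedMultiplexConfig(N=30, L=2, Q=2, seed=4))
        fit = sbm.fit_multiplex_sbm(mplex, Q=3, n_restarts=2, seed=0)
        assert np.allclose(fit.tau.sum(axis=1), 1.0, atol=1e-8)
        assert fit.pi.sum() == pytest.approx(1.0)
        assert np.all(fit.lam >= 0)
        assert np.allclose(fit.lam, fit.lam.transpose(0, 2, 1))


class TestIclAndSelection:
    def test_q1_icl_closed_form(self):
        mplex, _ = generate_planted_multiplex(
            PlantedMultiplexConfig(N=20, L=2, Q=1,
                                   lam=np.full((2, 1, 1), 1.0), seed=0))
        fit = sbm.fit_multiplex_sbm(mplex, Q=1, seed=0)
        from scipy.special import gammaln
        N = 20
        expected = 0.0
        for l in range(2):
            iu = np.triu_indices(N, 1)
            a = mplex.layers[l].adjacency[iu]
            rate = a.mean()
            expected += np.sum(a * np.log(rate) - rate - gammaln(a + 1.0))
        expected -= 0.5 * 2 * 1 * np.log(N * (N - 1) / 2)
        assert fit.icl == pytest.approx(expected)

    def test_penalty_increases_with_q_at_fixed_likelihood(self):
        N, L = 50, 3
        pens = [0.5 * L * (Q * (Q + 1) / 2) * np.log(N * (N - 1) / 2)
                + (Q - 1) / 2 * np.log(N) for Q in range(1, 6)]
        assert all(b > a for a, b in zip(pens, pens[1:]))

    def test_icl_invariant_under_relabeling(self):
        mplex, _ = generate_planted_multiplex(
            PlantedMultiplexConfig(N=30, L=2, Q=2, seed=6))
        fit = sbm.fit_multiplex_sbm(mplex, Q=2, n_restarts=2, seed=1)
        perm = [1, 0]
        permuted = sbm.SBMResults(
            model=fit.model, Q=2, tau=fit.tau[:, perm], pi=fit.pi[perm],
            lam=fit.lam[:, perm][:, :, perm], elbo_trace=fit.elbo_trace,
            converged=True, n_iter=fit.n_iter)
        assert sbm.icl(permuted) == pytest.approx(fit.icl)

    def test_select_returns_table_and_singleton_range(self):
        mplex, _ = generate_planted_multiplex(
            PlantedMultiplexConfig(N=30, L=2, Q=2, seed=7))
        model = sbm.MultiplexSBM.from_multiplex(mplex)
        only = model.select([1], seed=0)
        assert only.Q == 1 and set(only.icl_table) == {1}
        fit = model.select([1, 2, 3], n_restarts=2, seed=0)
        assert len(fit.icl_table) == 3

    def test_planted_q3_selected(self):
        hits = 0
        for seed in range(10):
            mplex, _ = generate_planted_multiplex(
                PlantedMultiplexConfig(N=90, L=3, Q=3, lam_in=4.0,
                                       lam_out=0.3, seed=200 + seed))
            fit = sbm.select_model(mplex, range(1, 6), n_restarts=3, seed=seed)
            hits += fit.Q == 3
        assert hits >= 8

    def test_summary_mentions_blocks_and_icl(self):
        mplex, _ = generate_planted_multiplex(
            PlantedMultiplexConfig(N=20, L=2, Q=2, seed=8))
        fit = sbm.fit_multiplex_sbm(mplex, Q=2, n_restarts=2, seed=0)
        text = fit.summary()
        assert "blocks" in text and "ICL" in text and "ELBO" in text
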
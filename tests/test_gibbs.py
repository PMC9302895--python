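"""Sampler correctness: FFBS against brute-force enumeration, conjugate
updates, prior reproduction, determinism, parameter recovery."""

import math

import numpy as np
import pytest
from blinkcount import (
    BenchmarkConfig,
    InferenceConfig,
    PhotoStateModel,
    TraceSet,
    build_params,
    ffbs_joint,
    load_prior_prob,
    make_benchmark,
    run_gibbs,
    sample_kinetics,
)
from blinkcount.gibbs import sample_brightness, _roi_loglik
from blinkcount.states import LatentConfiguration


# the exhaustive-enumeration oracle lives in _enumeration.py (shared
# with the acceptance suite)
from _enumeration import enumerate_joint


@pytest.mark.parametrize("j", [1, 2])
def test_ffbs_matches_enumeration(j, three_state, rng):
    """Joint (load, trajectory) draws match the exact tiny-problem posterior."""
    params = build_params(three_state, [30.0], [20.0], 2.0,
                          p_bleach=0.3, p_bright_to_dark=0.2,
                          p_dark_to_bright=0.4, dark_start_fraction=0.3)
    w = np.array([120.0, 45.0, 60.0])
    gamma, k_total = 2.0, 2
    cfg_probs, marg = enumerate_joint(w, params, three_state, gamma,
                                      k_total, j)

    M = 10_000
    cfg_counts = {}
    state_counts = np.zeros((3, three_state.S))
    for _ in range(M):
        loads, trajs = ffbs_joint(w, None, params, three_state, rng,
                                  gamma=gamma, k_total=k_total, j=j)
        key = tuple(int(b) for b in loads)
        cfg_counts[key] = cfg_counts.get(key, 0) + 1
        for n in range(3):
            state_counts[n, trajs[0, n]] += 1

    for cfg, p in cfg_probs.items():
        phat = cfg_counts.get(cfg, 0) / M
        se = math.sqrt(max(p * (1 - p), 1e-12) / M)
        assert abs(phat - p) < 4 * se + 1e-9, (cfg, phat, p)
    for n in range(3):
        for s in range(three_state.S):
            p = marg[n, s]
            phat = state_counts[n, s] / M
            se = math.sqrt(max(p * (1 - p), 1e-12) / M)
            assert abs(phat - p) < 4 * se + 1e-9, (n, s, phat, p)


def test_ffbs_prior_reproduction_without_likelihood(three_state, rng):
    """With the likelihood off, loads are Bernoulli(gamma/(K+gamma-1))."""
    params = build_params(three_state, [450.0], [1000.0], 50.0,
                          p_bleach=0.1, p_bright_to_dark=0.1,
                          p_dark_to_bright=0.2)
    w = np.full(4, 5e4)
    gamma, k_total = 5.0, 20
    q = load_prior_prob(gamma, k_total)
    M = 10_000
    on = 0
    for _ in range(M):
        loads, _ = ffbs_joint(w, None, params, three_state, rng,
                              gamma=gamma, k_total=k_total, j=2,
                              likelihood_on=False)
        on += int(loads.sum())
    phat = on / (2 * M)
    se = math.sqrt(q * (1 - q) / (2 * M))
    assert abs(phat - q) < 4 * se


def test_ffbs_final_frame_constraint(three_state, rng):
    params = build_params(three_state, [450.0], [1000.0], 50.0,
                          p_bleach=0.05, p_bright_to_dark=0.05,
                          p_dark_to_bright=0.1)
    w = np.full(30, 5e4)
    for _ in range(50):
        _, trajs = ffbs_joint(w, None, params, three_state, rng,
                              gamma=5.0, k_total=10, j=2)
        assert (trajs[:, -1] == three_state.bleached_index).all()


def test_ffbs_bleach_step_localisation(three_state, rng):
    """With one unmistakable bleach step the sampled step concentrates."""
    params = build_params(three_state, [450.0], [1000.0], 50.0,
                          p_bleach=0.02, p_bright_to_dark=0.01,
                          p_dark_to_bright=0.05)
    N, t_true = 100, 50
    mu = np.full(N, 1000.0)
    mu[:t_true] += 450.0
    w = np.random.default_rng(7).gamma(mu / 2, 2 * 50.0)
    hits = 0
    M = 200
    for _ in range(M):
        loads, trajs = ffbs_joint(w, None, params, three_state, rng,
                                  gamma=1.0, k_total=1, j=1)
        assert loads[0] == 1  # K=1, gamma=1 makes the load certain
        bright = np.flatnonzero(trajs[0] == 1)
        if bright.size and abs(bright[-1] + 1 - t_true) <= 2:
            hits += 1
    assert hits / M > 0.9


class TestSampleKinetics:
    def test_no_loaded_chains_draws_from_prior(self, three_state, rng):
        lat = LatentConfiguration(
            np.zeros((1, 4), np.uint8),
            np.full((1, 4, 6), 2, np.int8), gamma=5.0,
        )
        config = InferenceConfig(k_loads=4, n_sweeps=2, n_burn=0)
        draws = np.array([
            sample_kinetics(lat, three_state, config, rng)[0][1, 0]
            for _ in range(4000)
        ])
        # bright-row Dirichlet(1,1,1) marginal => Beta(1,2): mean 1/3
        assert abs(draws.mean() - 1 / 3) < 4 * draws.std() / 63.2

    def test_posterior_concentrates_on_empirical_rates(self, three_state, rng):
        # one loaded chain with 10^5 bright->bright transitions + 1 bleach
        traj = np.concatenate([
            np.ones(100_000, dtype=np.int8), [2]
        ])[None, None, :]
        lat = LatentConfiguration(np.ones((1, 1), np.uint8), traj, 5.0)
        config = InferenceConfig(k_loads=1, n_sweeps=2, n_burn=0)
        pis = np.array([
            sample_kinetics(lat, three_state, config, rng)[0]
            for _ in range(300)
        ])
        # bright->bright frequency in the trajectory is (n-2)/(n-1) ~ 1
        n11 = 100_000 - 1
        a = 1 + n11
        tot = 3 + 100_000
        post_mean = a / tot
        post_sd = math.sqrt(a * (tot - a) / (tot**2 * (tot + 1)))
        assert abs(pis[:, 1, 1].mean() - post_mean) < 3 * post_sd

    def test_absorbing_row_and_structural_zeros(self, three_state, rng):
        lat = LatentConfiguration(
            np.ones((1, 2), np.uint8),
            np.array([[[1, 1, 2, 2], [0, 1, 1, 2]]], dtype=np.int8), 5.0,
        )
        config = InferenceConfig(k_loads=2, n_sweeps=2, n_burn=0)
        pi, pi0 = sample_kinetics(lat, three_state, config, rng)
        assert np.array_equal(pi[2], [0.0, 0.0, 1.0])
        assert pi[0, 2] == 0.0  # dark -> bleached forbidden
        assert np.allclose(pi.sum(axis=1), 1.0)
        assert pi0[2] == 0.0 and np.isclose(pi0.sum(), 1.0)


class TestSampleBrightness:
    def test_background_recovery_within_two_percent(self, three_state):
        # single ROI, trajectories known (all bleached): mu_B alone
        rng = np.random.default_rng(5)
        N = 20_000
        mu_true = 1000.0
        w = rng.gamma(mu_true / 2, 2 * 50.0, size=N)
        ts = TraceSet(w[None, :], 0.05, 50.0)
        config = InferenceConfig(k_loads=1, n_sweeps=2, n_burn=0)
        params = build_params(three_state, [450.0], [1100.0], 50.0,
                              p_bleach=0.1)
        counts = np.zeros((1, N, 2), np.int32)
        priors = {
            "mu_A": [(2.0, 225.0)], "mu_B": [(2.0, 550.0)],
            "mh_scales": {"mu_A1": 0.02, "mu_B": 0.005},
        }
        accept = {"mu_A1": [0, 0], "mu_B": [0, 0]}
        logw = np.log(w[None, :])
        cur = np.array([_roi_loglik(w, logw[0], counts[0], 1100.0,
                                    np.array([450.0, 0.0]), 50.0)])
        chain = []
        for _ in range(600):
            sample_brightness(ts, counts, params, config, three_state, rng,
                              priors, accept, cur, logw, w[None, :])
            chain.append(params.mu_B[0])
        est = np.mean(chain[200:])
        assert abs(est - mu_true) / mu_true < 0.02

    def test_likelihood_dominance_at_truth(self, three_state):
        rng = np.random.default_rng(6)
        N = 20_000
        w = rng.gamma(1000.0 / 2, 2 * 50.0, size=N)
        counts = np.zeros((N, 2), np.int32)
        logw = np.log(w)
        ll_true = _roi_loglik(w, logw, counts, 1000.0,
                              np.array([450.0, 0.0]), 50.0)
        ll_off = _roi_loglik(w, logw, counts, 1500.0,
                             np.array([450.0, 0.0]), 50.0)
        assert ll_true > ll_off


class TestRunGibbs:
    def test_single_fluorophore_recovery(self, rng):
        ts = make_benchmark(BenchmarkConfig(
            n_rois=1, n_frames=600, n_sites=1, labeling_eff=1.0,
            mu_A=(450.0,), seed=21))
        assert ts.ground_truth.counts[0] == 1
        cfg = InferenceConfig(k_loads=8, gamma=2.0, n_sweeps=300, n_burn=150,
                              seed=2)
        draws = run_gibbs(ts, cfg,
                          state_model=PhotoStateModel.three_state())
        vals, cnts = np.unique(draws.counts[:, 0], return_counts=True)
        assert vals[np.argmax(cnts)] == 1

    def test_bit_reproducible_and_thread_invariant(self):
        ts = make_benchmark(BenchmarkConfig(n_rois=2, n_frames=200,
                                            n_sites=4, seed=31))
        kw = dict(k_loads=8, n_sweeps=40, n_burn=10, seed=3)
        a = run_gibbs(ts, InferenceConfig(**kw))
        b = run_gibbs(ts, InferenceConfig(**kw))
        c = run_gibbs(ts, InferenceConfig(**kw, n_jobs=2))
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.loads, c.loads)
        assert np.array_equal(a.mu_A, c.mu_A)

    def test_every_retained_draw_ends_bleached(self):
        ts = make_benchmark(BenchmarkConfig(n_rois=1, n_frames=200,
                                            n_sites=4, seed=33))
        cfg = InferenceConfig(k_loads=6, n_sweeps=40, n_burn=10, thin_traj=2,
                              seed=4)
        draws = run_gibbs(ts, cfg)
        b = draws.state_model.bleached_index
        for arr in draws.traj_draws:
            assert (arr[:, :, -1] == b).all()

    def test_load_relabelling_leaves_counts_invariant(self):
        ts = make_benchmark(BenchmarkConfig(n_rois=1, n_frames=200,
                                            n_sites=4, seed=33))
        cfg = InferenceConfig(k_loads=6, n_sweeps=30, n_burn=10, seed=4)
        draws = run_gibbs(ts, cfg)
        perm = np.random.default_rng(0).permutation(cfg.k_loads)
        assert np.array_equal(draws.loads[:, :, perm].sum(axis=2),
                              draws.counts)

    def test_gibbs_prior_reproduction(self):
        """Full sampler with likelihood off: load marginal = gamma/(K+g-1)."""
        ts = make_benchmark(BenchmarkConfig(n_rois=2, n_frames=60, n_sites=3,
                                            seed=35))
        gamma, K = 3.0, 10
        cfg = InferenceConfig(k_loads=K, gamma=gamma, n_sweeps=400,
                              n_burn=0, likelihood_on=False, seed=5)
        draws = run_gibbs(ts, cfg)
        q = load_prior_prob(gamma, K)
        # with a flat likelihood each sweep redraws loads from the prior
        phat = draws.loads.mean()
        n = draws.loads.size
        se = math.sqrt(q * (1 - q) / n)
        assert abs(phat - q) < 4 * se


def test_parameter_recovery_calibration(three_state):
    """95% credible intervals cover true kinetics/brightness >= 80% of the
    time over replicate simulations (small-data calibration check)."""
    hits_pbd = 0
    hits_mua = 0
    reps = 20
    for i in range(reps):
        ts = make_benchmark(BenchmarkConfig(
            n_rois=2, n_frames=1000, n_sites=5, labeling_eff=0.8,
            mu_A=(450.0,), seed=500 + i))
        truth = ts.ground_truth.params
        cfg = InferenceConfig(k_loads=12, gamma=4.0, n_sweeps=300,
                              n_burn=150, seed=i)
        draws = run_gibbs(ts, cfg, state_model=three_state)
        lo, hi = np.quantile(draws.pi[:, 1, 0], [0.025, 0.975])
        hits_pbd += int(lo <= truth.pi[1, 0] <= hi)
        lo, hi = np.quantile(draws.mu_A[:, 0], [0.025, 0.975])
        hits_mua += int(lo <= truth.mu_A[0] <= hi)
    assert hits_pbd >= int(0.8 * reps)
    assert hits_mua >= int(0.8 * reps)
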
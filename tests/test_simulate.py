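"""Forward-model simulator: counts, trajectories, readouts, ROI sums."""

import math

import numpy as np
import pytest
from scipy import stats

from blinkcount import (
    BenchmarkConfig,
    PhotoStateModel,
    build_params,
    combine_rois,
    combine_traceset,
    make_benchmark,
    readout_moments,
    sample_fluorophore_count,
    simulate_trace,
    simulate_trajectory,
)


class TestFluorophoreCounts:
    def test_full_labeling_is_deterministic(self, rng):
        assert all(sample_fluorophore_count(20, 1.0, rng) == 20
                   for _ in range(10))

    def test_zero_labeling(self, rng):
        assert sample_fluorophore_count(20, 0.0, rng) == 0

    def test_mean_matches_binomial(self, rng):
        draws = [sample_fluorophore_count(20, 0.7, rng) for _ in range(10_000)]
        se = math.sqrt(20 * 0.7 * 0.3 / len(draws))
        assert abs(np.mean(draws) - 14.0) < 3 * se

    def test_counts_binomial_goodness_of_fit(self):
        ts = make_benchmark(BenchmarkConfig(n_rois=300, n_frames=2, seed=9))
        counts = ts.ground_truth.counts
        ks = np.arange(21)
        pmf = stats.binom.pmf(ks, 20, 0.7)
        # pool tails so expected counts stay reasonable
        obs = np.bincount(counts, minlength=21).astype(float)
        keep = pmf * len(counts) >= 5
        obs_p = np.concatenate([[obs[~keep].sum()], obs[keep]])
        exp_p = np.concatenate([[pmf[~keep].sum()], pmf[keep]]) * len(counts)
        chi2 = ((obs_p - exp_p) ** 2 / exp_p).sum()
        crit = stats.chi2.ppf(0.99, df=len(exp_p) - 1)
        assert chi2 < crit


class TestTrajectories:
    def test_deterministic_kinetics(self, three_state, rng):
        params = build_params(three_state, [450.0], [1000.0], 50.0,
                              p_bleach=1.0)
        traj = simulate_trajectory(params, 5, rng)[0]
        assert traj[0] == 1 and (traj[1:] == 2).all()

    def test_initial_bright_fraction(self, three_state, rng):
        params = build_params(three_state, [450.0], [1000.0], 50.0,
                              p_bleach=0.01, p_bright_to_dark=0.02,
                              p_dark_to_bright=0.02, dark_start_fraction=0.4)
        starts = simulate_trajectory(params, 1, rng, n_chains=10_000)[:, 0]
        frac_bright = (starts == 1).mean()
        se = math.sqrt(0.6 * 0.4 / 10_000)
        assert abs(frac_bright - 0.6) < 3 * se

    def test_bright_dwells_geometric(self, three_state, rng):
        p_stay = 0.9
        params = build_params(three_state, [450.0], [1000.0], 50.0,
                              p_bleach=0.04, p_bright_to_dark=0.06,
                              p_dark_to_bright=0.05)
        trajs = simulate_trajectory(params, 400, rng, n_chains=600)
        dwells = []
        for tr in trajs:
            run = 0
            for s in tr:
                if s == 1:
                    run += 1
                elif run:
                    dwells.append(run)
                    run = 0
        dwells = np.array(dwells, float)
        expect = 1.0 / (1.0 - p_stay)
        se = expect / math.sqrt(dwells.size)  # geometric sd ~ mean
        assert abs(dwells.mean() - expect) < 3 * se

    def test_bleached_is_absorbing(self, simple_params, rng):
        trajs = simulate_trajectory(simple_params, 200, rng, n_chains=200)
        for tr in trajs:
            hit = np.flatnonzero(tr == 2)
            if hit.size:
                assert (tr[hit[0]:] == 2).all()


class TestTraces:
    def test_background_only_mean(self, simple_params, three_state, rng):
        traj = np.full((0, 10_000), 2, dtype=np.int8)
        w = simulate_trace(traj, simple_params, rng, three_state)
        mean, sd = readout_moments(1000.0, 50.0)
        assert abs(w.mean() - mean) < 3 * sd / math.sqrt(w.size)

    def test_variance_mean_ratio_is_2G(self, simple_params, three_state, rng):
        traj = np.full((0, 40_000), 2, dtype=np.int8)
        w = simulate_trace(traj, simple_params, rng, three_state)
        ratio = w.var(ddof=1) / w.mean()
        assert ratio == pytest.approx(2 * 50.0, rel=0.05)

    def test_step_level_above_background(self, three_state, rng):
        params = build_params(three_state, [450.0], [1000.0], 50.0,
                              p_bleach=1e-9)
        traj = np.ones((3, 5000), dtype=np.int8)  # three always-bright dyes
        w = simulate_trace(traj, params, rng, three_state)
        mean, sd = readout_moments(1000.0 + 3 * 450.0, 50.0)
        assert abs(w.mean() - mean) < 3 * sd / math.sqrt(w.size)


class TestCombineRois:
    def test_sum_of_backgrounds(self, simple_params, three_state, rng):
        traj = np.full((0, 20_000), 2, dtype=np.int8)
        t1 = simulate_trace(traj, simple_params, rng, three_state)
        t2 = simulate_trace(traj, simple_params, rng, three_state)
        combined = combine_rois([t1, t2], [50.0, 50.0])
        mean, sd = readout_moments(2000.0, 50.0)
        assert abs(combined.mean() - mean) < 3 * sd / math.sqrt(combined.size)
        assert combined.var(ddof=1) == pytest.approx(sd**2, rel=0.1)

    def test_single_trace_identity(self):
        t = np.array([1.0, 2.0, 3.0])
        assert np.array_equal(combine_rois([t], [50.0]), t)

    def test_differing_gains_rejected(self):
        t = np.ones(4)
        with pytest.raises(ValueError, match="gain"):
            combine_rois([t, t], [50.0, 10.0])

    def test_ground_truth_counts_add(self, tiny_benchmark):
        combined = combine_traceset(tiny_benchmark, [[0, 1]])
        gt = tiny_benchmark.ground_truth
        assert combined.ground_truth.counts[0] == gt.counts.sum()
        assert np.allclose(combined.w[0],
                           tiny_benchmark.w[0] + tiny_benchmark.w[1])


class TestMakeBenchmark:
    def test_replica_configuration(self):
        cfg = BenchmarkConfig()
        assert (cfg.n_rois, cfg.n_frames, cfg.gain) == (50, 20000, 50.0)
        assert cfg.mu_A == (450.0, 350.0)
        assert cfg.mu_background == 1000.0
        params = cfg.params()
        assert params.pi0[-1] == 0.0

    def test_fixed_seed_reproducible(self):
        a = make_benchmark(BenchmarkConfig(n_rois=2, n_frames=100, seed=5))
        b = make_benchmark(BenchmarkConfig(n_rois=2, n_frames=100, seed=5))
        assert np.array_equal(a.w, b.w)
        assert np.array_equal(a.ground_truth.counts, b.ground_truth.counts)

    def test_roi_substreams_stable_under_R(self):
        a = make_benchmark(BenchmarkConfig(n_rois=2, n_frames=100, seed=5))
        b = make_benchmark(BenchmarkConfig(n_rois=4, n_frames=100, seed=5))
        assert np.array_equal(a.w, b.w[:2])

    def test_zero_labeling_gives_pure_background(self):
        ts = make_benchmark(BenchmarkConfig(n_rois=1, n_frames=500,
                                            labeling_eff=0.0, seed=3))
        assert ts.ground_truth.counts[0] == 0
        mean, sd = readout_moments(1000.0, 50.0)
        assert abs(ts.w.mean() - mean) < 4 * sd / math.sqrt(ts.N)

    def test_high_noise_scaling_preserves_mean_level(self):
        base = BenchmarkConfig(n_rois=1, n_frames=2000, seed=3)
        noisy = BenchmarkConfig(n_rois=1, n_frames=2000, seed=3,
                                noise_scale=10)
        pb, pn = base.params(), noisy.params()
        assert pn.mu_A[0] * pn.gain == pytest.approx(pb.mu_A[0] * pb.gain)
        assert pn.mu_B[0] * pn.gain == pytest.approx(pb.mu_B[0] * pb.gain)
        # relative noise grows as sqrt(nu)
        _, sd_b = readout_moments(pb.mu_B[0], pb.gain)
        _, sd_n = readout_moments(pn.mu_B[0], pn.gain)
        assert sd_n / sd_b == pytest.approx(math.sqrt(10), rel=1e-9)

    def test_all_trajectories_bleach_by_trace_end(self):
        ts = make_benchmark(BenchmarkConfig(n_rois=5, n_frames=2000, seed=8))
        last = np.concatenate(
            [t[:, -1] for t in ts.ground_truth.trajectories if t.size])
        assert (last == 3).mean() > 0.98
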
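"""Forward simulation of brightness traces from blinking, bleaching dyes.

Reproduces the benchmark construction used throughout: each ROI mimics a
DNA-origami construct with ``n_sites`` fluorophore binding sites labelled
with efficiency ``labeling_eff`` (true count Binomial), each fluorophore
runs an independent Markov photo-trajectory, and each frame's summed ROI
brightness is read out through the EMCCD gamma model.

Kinetic rates are not part of the published benchmark; the defaults are
set so that (a) every fluorophore photobleaches well before the end of the
trace (expected photo-lifetime ~N/10 frames including dark excursions) and
(b) blinking is frequent enough that methods ignoring dark states visibly
undercount. See docs/methods.md for the reasoning behind each value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .states import GroundTruth, ModelParams, PhotoStateModel, TraceSet

__all__ = [
    "BenchmarkConfig",
    "default_kinetics",
    "build_params",
    "sample_fluorophore_count",
    "simulate_trajectory",
    "simulate_trace",
    "combine_rois",
    "combine_traceset",
    "make_benchmark",
]


def default_kinetics(state_model: PhotoStateModel, n_frames: int) -> dict:
    """Per-frame transition rates scaled to the trace length.

    bleach: 20/N (expected photo-lifetime ~N/10 frames once dark dwells
    are counted); bright->dark: 2x the bleach rate; dark->bright: 2x the
    bleach rate (dark dwell ~N/40 frames, stationary dark fraction 1/2
    among unbleached fluorophores — dyes of this class spend a large
    share of their pre-bleach life dark); bright<->bright interconversion
    (two bright states only): 2x the bleach rate.
    """
    p_bleach = min(20.0 / n_frames, 0.1)  # cap keeps short traces valid
    return {
        "p_bleach": p_bleach,
        "p_bright_to_dark": 2.0 * p_bleach,
        "p_dark_to_bright": 2.0 * p_bleach,
        "p_interconvert": 2.0 * p_bleach,
    }


def build_params(
    state_model: PhotoStateModel,
    mu_A: Sequence[float],
    mu_B: Sequence[float],
    gain: float,
    *,
    p_bleach: float,
    p_bright_to_dark: float = 0.0,
    p_dark_to_bright: float = 0.0,
    p_interconvert: float = 0.0,
    dark_start_fraction: float = 0.0,
) -> ModelParams:
    """Assemble a row-stochastic transition matrix from named rates."""
    S = state_model.S
    b = state_model.bleached_index
    bright = state_model.bright_states
    dark = [s for s in range(S) if s != b and s not in bright]
    pi = np.zeros((S, S))
    for d in dark:
        share = p_dark_to_bright / len(bright)
        for a in bright:
            pi[d, a] = share
        pi[d, d] = 1.0 - p_dark_to_bright
    for a in bright:
        pi[a, b] = p_bleach
        for d in dark:
            pi[a, d] = p_bright_to_dark / max(len(dark), 1)
        others = [a2 for a2 in bright if a2 != a and state_model.allowed[a, a2]]
        for a2 in others:
            pi[a, a2] = p_interconvert / len(others)
        pi[a, a] = 1.0 - pi[a].sum()
    pi[b, b] = 1.0
    pi[~state_model.allowed] = 0.0
    pi0 = np.zeros(S)
    if dark:
        pi0[dark[0]] = dark_start_fraction
    bright_mass = 1.0 - (dark_start_fraction if dark else 0.0)
    for a in bright:
        pi0[a] = bright_mass / len(bright)
    params = ModelParams(pi0, pi, np.asarray(mu_A, float),
                         np.asarray(mu_B, float), gain)
    params.validate(state_model)
    return params


@dataclass
class BenchmarkConfig:
    """Study conditions for the synthetic benchmark.

    Defaults replicate the published simulation: 50 ROIs of 20 binding
    sites at 70% labelling efficiency, 20000 frames at 50 ms, gain 50,
    background 1000 photons/frame, two bright states at 450 and 350
    photons/frame. ``noise_scale`` nu rescales mu -> mu/nu and G -> G*nu,
    holding the mean ADU level fixed while inflating relative shot noise
    (the high-noise regime). ``dark_start_fraction`` sets the share of
    fluorophores that begin in the dark state.
    """

    n_rois: int = 50
    n_frames: int = 20000
    frame_period: float = 0.05
    n_sites: int = 20
    labeling_eff: float = 0.7
    gain: float = 50.0
    mu_background: float = 1000.0
    mu_A: tuple = (450.0, 350.0)
    dark_start_fraction: float = 0.0
    noise_scale: float = 1.0
    kinetics: Optional[dict] = None
    state_model: Optional[PhotoStateModel] = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.labeling_eff <= 1.0:
            raise ValueError("labeling_eff must be a probability")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be positive")
        if self.state_model is None:
            self.state_model = (
                PhotoStateModel.four_state() if len(self.mu_A) == 2
                else PhotoStateModel.three_state()
            )
        if self.kinetics is None:
            self.kinetics = default_kinetics(self.state_model, self.n_frames)

    def params(self) -> ModelParams:
        nu = self.noise_scale
        mu_A = np.asarray(self.mu_A, float) / nu
        mu_B = np.full(self.n_rois, self.mu_background / nu)
        return build_params(
            self.state_model, mu_A, mu_B, self.gain * nu,
            dark_start_fraction=self.dark_start_fraction, **self.kinetics,
        )


def sample_fluorophore_count(
    n_sites: int, labeling_eff: float, rng: np.random.Generator
) -> int:
    """True fluorophore count of one ROI: Binomial(sites, efficiency)."""
    if not 0.0 <= labeling_eff <= 1.0:
        raise ValueError("labeling_eff must be a probability")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    return int(rng.binomial(n_sites, labeling_eff))


def simulate_trajectory(
    params: ModelParams,
    n_frames: int,
    rng: np.random.Generator,
    n_chains: int = 1,
) -> np.ndarray:
    """Sample Markov photo-trajectories; shape (n_chains, n_frames).

    Forward simulation does not condition on ending bleached — benchmark
    kinetics make bleaching within the trace overwhelmingly likely.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    S = params.pi.shape[0]
    cum0 = np.cumsum(params.pi0)
    cum = np.cumsum(params.pi, axis=1)
    out = np.empty((n_chains, n_frames), dtype=np.int8)
    state = np.searchsorted(cum0, rng.random(n_chains), side="right")
    state = np.minimum(state, S - 1)
    out[:, 0] = state
    for n in range(1, n_frames):
        u = rng.random(n_chains)
        rows = cum[state]
        state = (u[:, None] >= rows).sum(axis=1)
        state = np.minimum(state, S - 1)
        out[:, n] = state
    return out


def simulate_trace(
    trajectories: np.ndarray,
    params: ModelParams,
    rng: np.random.Generator,
    state_model: PhotoStateModel,
    roi: int = 0,
) -> np.ndarray:
    """Readout one ROI: framewise Gamma(mu_n/2, 2G) with summed brightness."""
    trajectories = np.atleast_2d(np.asarray(trajectories))
    bright = state_model.state_brightness(params.mu_A)
    mu = params.mu_B[roi] + bright[trajectories].sum(axis=0)
    return rng.gamma(shape=mu / 2.0, scale=2.0 * params.gain)


def combine_rois(traces: Sequence[np.ndarray], gains: Sequence[float]) -> np.ndarray:
    """Framewise sum of ROI traces sharing one gain.

    The gamma readout is closed under addition at a common scale 2G, so
    the sum is distributed exactly as a single ROI holding the union of
    fluorophores with summed background.
    """
    traces = [np.asarray(t, float) for t in traces]
    if len({t.shape for t in traces}) != 1:
        raise ValueError("traces must share a common length")
    gains = np.asarray(list(gains), float)
    if gains.size != len(traces) or not np.all(gains == gains[0]):
        raise ValueError("combining ROIs requires identical gains")
    return np.sum(traces, axis=0)


def combine_traceset(ts: TraceSet, groups: Sequence[Sequence[int]]) -> TraceSet:
    """Build a new TraceSet whose ROIs are sums over index groups.

    Ground-truth counts add; backgrounds add; trajectories concatenate.
    """
    w = np.stack([
        combine_rois([ts.w[i] for i in g], [ts.gain] * len(g)) for g in groups
    ])
    gt = None
    if ts.ground_truth is not None:
        old = ts.ground_truth
        counts = np.array([sum(old.counts[i] for i in g) for g in groups])
        mu_B = np.array([sum(old.params.mu_B[i] for i in g) for g in groups])
        params = ModelParams(old.params.pi0, old.params.pi, old.params.mu_A,
                             mu_B, old.params.gain)
        trajs = None
        if old.trajectories is not None:
            trajs = [
                np.concatenate([old.trajectories[i] for i in g], axis=0)
                for g in groups
            ]
        gt = GroundTruth(counts, params, old.state_model, trajs)
    return TraceSet(w, ts.frame_period, ts.gain, gt)


def make_benchmark(config: BenchmarkConfig) -> TraceSet:
    """Simulate the full benchmark: counts, trajectories, readouts.

    Each ROI draws from its own RNG substream of the master seed, so
    changing ``n_rois`` never perturbs earlier ROIs.
    """
    params = config.params()
    model = config.state_model
    streams = np.random.SeedSequence(config.seed).spawn(config.n_rois)
    w = np.empty((config.n_rois, config.n_frames))
    counts = np.empty(config.n_rois, dtype=int)
    trajs = []
    for r, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        k_r = sample_fluorophore_count(config.n_sites, config.labeling_eff, rng)
        counts[r] = k_r
        traj = (simulate_trajectory(params, config.n_frames, rng, k_r)
                if k_r > 0 else
                np.empty((0, config.n_frames), dtype=np.int8))
        trajs.append(traj)
        w[r] = simulate_trace(traj, params, rng, model, roi=r)
    gt = GroundTruth(counts, params, model, trajs)
    return TraceSet(w, config.frame_period, config.gain, gt)
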
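"""FFBS-within-Gibbs inference of loads, trajectories, kinetics, brightness.

The sampler alternates three blocks:

1. ``sweep_states`` — for every ROI, loads are visited in groups of J
   (default 2) and each group's (load, trajectory) pair is drawn exactly
   from its full conditional. Within a group the load configuration is
   sampled from the marginal likelihoods of the 2**J configurations (the
   load is constant over the trace, so filtering runs over photo-states
   for each configuration, not over a load-augmented state space), then
   trajectories are backward-sampled: loaded chains from their filters,
   unloaded chains from the kinetic prior conditioned to end bleached.
2. ``sample_kinetics`` — conjugate Dirichlet updates of the transition
   matrix rows (on their allowed support) and of the initial distribution,
   from transitions pooled over loaded fluorophores in all ROIs.
3. ``sample_brightness`` — Metropolis-within-Gibbs log-normal random-walk
   updates of the bright-state brightnesses and each ROI background (the
   gamma emission is not conjugate).

All randomness flows from one master seed through named substreams
(per ROI, plus one each for kinetics and brightness), so reruns are
bit-reproducible and ROIs may be processed in parallel threads with
results identical to sequential processing.
"""

from __future__ import annotations

import logging
import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import gammaln

from . import _kernels
from .emission import clamp_readouts, load_prior_prob
from .simulate import default_kinetics, build_params
from .states import (
    LatentConfiguration,
    ModelParams,
    PhotoStateModel,
    TraceSet,
)

logger = logging.getLogger(__name__)

__all__ = [
    "InferenceConfig",
    "PosteriorDraws",
    "ffbs_joint",
    "sweep_states",
    "sample_kinetics",
    "sample_brightness",
    "run_gibbs",
]


@dataclass
class InferenceConfig:
    """Sampler settings and hyperparameters.

    ``k_loads`` is the weak-limit truncation (choose it to exceed any
    plausible fluorophore count; the posterior is insensitive to it once
    large enough). ``gamma`` is the Beta-Bernoulli concentration.
    ``j_joint`` loads are sampled jointly per FFBS pass (1 or 2).
    ``dirichlet_conc`` / ``pi0_conc`` are pseudo-counts on allowed
    transitions / initial states; ``brightness_prior_shape`` sets the
    gamma prior shape on brightnesses (scale is initial estimate / shape,
    centring the prior on the initialisation). ``mh_scale`` /
    ``mh_scale_background`` are initial log-normal proposal steps;
    proposal scales adapt during burn-in toward ~30% acceptance
    (Robbins-Monro on the log step) and freeze afterwards, so retained
    draws come from a fixed kernel. ``likelihood_on=False`` runs the
    sampler against the prior alone (used for prior-reproduction checks).
    """

    k_loads: int = 50
    gamma: float = 10.0
    j_joint: int = 2
    n_sweeps: int = 1000
    n_burn: Optional[int] = None
    dirichlet_conc: float = 1.0
    pi0_conc: float = 1.0
    brightness_prior_shape: float = 2.0
    mh_scale: float = 0.02
    mh_scale_background: float = 0.005
    thin_traj: int = 50
    constrain_final_bleached: bool = True
    likelihood_on: bool = True
    sample_params: bool = True
    n_jobs: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.k_loads < 1:
            raise ValueError("k_loads must be >= 1")
        if self.j_joint not in (1, 2):
            raise ValueError("j_joint must be 1 or 2")
        if self.n_burn is None:
            self.n_burn = self.n_sweeps // 2
        if not 0 <= self.n_burn < self.n_sweeps:
            raise ValueError("need 0 <= n_burn < n_sweeps")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass
class PosteriorDraws:
    """Post-burn-in Gibbs draws and derived per-ROI counts."""

    counts: np.ndarray          # (n_kept, R) B_r per sweep
    loads: np.ndarray           # (n_kept, R, K)
    mu_A: np.ndarray            # (n_kept, nb)
    mu_B: np.ndarray            # (n_kept, R)
    pi: np.ndarray              # (n_kept, S, S)
    pi0: np.ndarray             # (n_kept, S)
    log_posterior: np.ndarray   # (n_kept,)
    sweep_index: np.ndarray     # (n_kept,) absolute sweep numbers
    traj_sweeps: list           # sweep numbers with stored trajectories
    traj_draws: list            # matching (R, K, N) int8 arrays
    best: dict                  # highest log-posterior draw (trajs, params)
    accept_rates: dict          # MH acceptance fraction per parameter
    config: InferenceConfig
    state_model: PhotoStateModel
    final_latent: LatentConfiguration

    @property
    def n_kept(self) -> int:
        return self.counts.shape[0]

    @property
    def R(self) -> int:
        return self.counts.shape[1]


# ---------------------------------------------------------------------------
# state-model tables for the kernels

_TABLE_CACHE: dict = {}


def _tables(model: PhotoStateModel):
    """Bright-count level tables shared by all kernel calls.

    ``lev`` rows are (bright1, bright2) count increments; row 0 is always
    the zero level. ``pl[s1, s2]`` and ``sl[s]`` map joint / single photo
    states to level rows.
    """
    key = (model.labels, model.bright_map, model.allowed.tobytes())
    if key in _TABLE_CACHE:
        return _TABLE_CACHE[key]
    S = model.S
    nb = model.n_bright
    sc = np.array(model.bright_map, dtype=np.int64)

    def comp(*states):
        da = sum(1 for s in states if sc[s] == 0)
        db = sum(1 for s in states if sc[s] == 1)
        return (da, db)

    levels = [(0, 0)]
    for s1 in range(S):
        for s2 in range(S):
            for c in (comp(s1), comp(s1, s2)):
                if c not in levels:
                    levels.append(c)
    lev = np.array(levels, dtype=np.int64)
    index = {tuple(c): i for i, c in enumerate(levels)}
    pl = np.array(
        [[index[comp(s1, s2)] for s2 in range(S)] for s1 in range(S)],
        dtype=np.int64,
    )
    sl = np.array([index[comp(s)] for s in range(S)], dtype=np.int64)
    out = {"sc": sc, "lev": lev, "pl": pl, "sl": sl, "nb": nb}
    _TABLE_CACHE[key] = out
    return out


def _group_partition(K: int, J: int,
                     rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Partition the K loads into FFBS groups of J.

    When a generator is given the partition is drawn fresh (a random-scan
    pairing): over sweeps every pair of chains eventually shares a joint
    update, which lets the sampler split one chain's disjoint bright
    segments across two loads and greatly improves load mixing.
    """
    order = (rng.permutation(K) if rng is not None
             else np.arange(K, dtype=np.int64))
    if J == 1:
        return np.array([[k, -1] for k in order], dtype=np.int64)
    groups = [[order[k], order[k + 1]] for k in range(0, K - 1, 2)]
    if K % 2:
        groups.append([order[K - 1], -1])
    return np.array(groups, dtype=np.int64)


def _mu_a2(params: ModelParams, nb: int) -> np.ndarray:
    muA = np.zeros(2)
    muA[:nb] = params.mu_A
    return muA


# ---------------------------------------------------------------------------
# operations

def ffbs_joint(
    w_trace: np.ndarray,
    rest_counts: Optional[np.ndarray],
    params: ModelParams,
    state_model: PhotoStateModel,
    rng: np.random.Generator,
    *,
    gamma: float = 10.0,
    k_total: int = 2,
    j: int = 2,
    roi: int = 0,
    constrain_final_bleached: bool = True,
    likelihood_on: bool = True,
):
    """Draw J (load, trajectory) pairs exactly from their full conditional.

    ``rest_counts`` is the (N, 2) per-frame bright-state occupancy of all
    *other* loaded fluorophores in the ROI (None for zeros). Returns
    ``(loads, trajs)`` with shapes (J,) and (J, N).
    """
    t = _tables(state_model)
    w = clamp_readouts(np.asarray(w_trace, float))
    N = w.shape[0]
    if rest_counts is None:
        rest_counts = np.zeros((N, 2), dtype=np.int32)
    rest_counts = np.ascontiguousarray(rest_counts, dtype=np.int32)
    x = np.log(w) - math.log(2.0 * params.gain)
    loads = np.zeros(j, dtype=np.uint8)
    trajs = np.zeros((j, N), dtype=np.int8)
    groups = np.array([[0, 1 if j == 2 else -1]], dtype=np.int64)
    q = load_prior_prob(gamma, k_total)
    cache_dim = int(rest_counts.max(initial=0)) + j + 3
    status, _ = _kernels.sweep_states_roi(
        x, params.pi0, params.pi, float(params.mu_B[roi]),
        _mu_a2(params, t["nb"]), t["nb"], t["sc"], t["lev"], t["pl"],
        t["sl"], q, loads, trajs, groups, rest_counts, cache_dim,
        rng.random(1), rng.random((j, N)),
        likelihood_on, constrain_final_bleached,
    )
    if status != 0:
        raise FloatingPointError(
            f"zero filter mass in every load configuration at frame {status - 1}"
        )
    return loads, trajs


def sweep_states(
    traces: TraceSet,
    latent: LatentConfiguration,
    params: ModelParams,
    config: InferenceConfig,
    state_model: PhotoStateModel,
    roi_rngs: list,
) -> np.ndarray:
    """One FFBS pass over every load group of every ROI (in place).

    Returns the (R, N, 2) bright-state occupancy of loaded chains. ROIs
    are independent; with ``config.n_jobs > 1`` they are processed in
    worker threads, bit-identically to sequential processing because each
    ROI consumes only its own pre-drawn uniforms.
    """
    t = _tables(state_model)
    R, N = traces.w.shape
    K = latent.K
    n_groups = K if config.j_joint == 1 else (K + 1) // 2
    q = load_prior_prob(config.gamma, K)
    w = clamp_readouts(traces.w)
    muA = _mu_a2(params, t["nb"])
    counts_all = np.zeros((R, N, 2), dtype=np.int32)
    base = np.zeros((N, 2), dtype=np.int32)
    cache_dim = K + 3

    # pre-draw partitions and uniforms so execution order cannot matter
    us = [(_group_partition(K, config.j_joint, rng),
           rng.random(n_groups), rng.random((K, N)))
          for rng in roi_rngs]

    def run(r):
        x = np.log(w[r]) - math.log(2.0 * params.gain)
        status, counts = _kernels.sweep_states_roi(
            x, params.pi0, params.pi, float(params.mu_B[r]), muA, t["nb"],
            t["sc"], t["lev"], t["pl"], t["sl"], q,
            latent.loads[r], latent.trajs[r], us[r][0], base, cache_dim,
            us[r][1], us[r][2],
            config.likelihood_on, config.constrain_final_bleached,
        )
        if status != 0:
            raise FloatingPointError(
                f"ROI {r}: zero filter mass in every load configuration "
                f"at frame {status - 1}"
            )
        counts_all[r] = counts

    if config.n_jobs > 1:
        with ThreadPoolExecutor(max_workers=config.n_jobs) as ex:
            list(ex.map(run, range(R)))
    else:
        for r in range(R):
            run(r)
    return counts_all


def _pooled_counts(latent: LatentConfiguration, S: int):
    """Transition and initial-state counts over loaded fluorophores."""
    sel = latent.trajs[latent.loads.astype(bool)]
    if sel.size == 0:
        return np.zeros((S, S), dtype=np.int64), np.zeros(S, dtype=np.int64)
    idx = (sel[:, :-1].astype(np.int64) * S + sel[:, 1:]).ravel()
    trans = np.bincount(idx, minlength=S * S).reshape(S, S)
    init = np.bincount(sel[:, 0].astype(np.int64), minlength=S)
    return trans, init


def sample_kinetics(
    latent: LatentConfiguration,
    state_model: PhotoStateModel,
    config: InferenceConfig,
    rng: np.random.Generator,
):
    """Conjugate Dirichlet draw of (pi, pi0) given loaded trajectories.

    Forbidden transitions stay structural zeros; the absorbing row stays
    (0, ..., 0, 1); with no loaded fluorophores the draw is from the prior.
    """
    S = state_model.S
    b = state_model.bleached_index
    trans, init = _pooled_counts(latent, S)
    pi = np.zeros((S, S))
    for i in range(S):
        if i == b:
            pi[i, b] = 1.0
            continue
        sup = np.flatnonzero(state_model.allowed[i])
        conc = config.dirichlet_conc + trans[i, sup]
        pi[i, sup] = rng.dirichlet(conc)
    pi0 = np.zeros(S)
    sup = np.array([s for s in range(S) if s != b])
    conc = config.pi0_conc + init[sup]
    pi0[sup] = rng.dirichlet(conc) if sup.size > 1 else 1.0
    return pi, pi0


def _roi_loglik(w_r, logw_r, cnt_r, mu_B_r, muA, gain):
    """Exact gamma log-likelihood of one ROI trace given occupancy counts."""
    mu = mu_B_r + cnt_r[:, 0] * muA[0] + cnt_r[:, 1] * muA[1]
    a = 0.5 * mu
    log2g = math.log(2.0 * gain)
    return float(
        np.sum((a - 1.0) * logw_r) - w_r.sum() / (2.0 * gain)
        - a.sum() * log2g - gammaln(a).sum()
    )


def _gamma_logprior(x, shape, scale):
    return (shape - 1.0) * math.log(x) - x / scale


def sample_brightness(
    traces: TraceSet,
    counts_all: np.ndarray,
    params: ModelParams,
    config: InferenceConfig,
    state_model: PhotoStateModel,
    rng: np.random.Generator,
    priors: dict,
    accept: dict,
    cur_ll: np.ndarray,
    logw: np.ndarray,
    w: np.ndarray,
):
    """One MH pass over mu_A (each bright state) and mu_B (each ROI).

    Proposals are log-normal random walks; the acceptance ratio includes
    the log-normal Jacobian. ``cur_ll`` (per-ROI log-likelihood) is kept
    current in place.
    """
    nb = state_model.n_bright
    R = traces.R
    gain = params.gain
    muA = _mu_a2(params, nb)
    scales = priors["mh_scales"]

    for jb in range(nb):
        name = f"mu_A{jb + 1}"
        old = params.mu_A[jb]
        new = old * math.exp(scales[name] * rng.standard_normal())
        muA_new = muA.copy()
        muA_new[jb] = new
        new_ll = np.array([
            _roi_loglik(w[r], logw[r], counts_all[r], params.mu_B[r],
                        muA_new, gain)
            for r in range(R)
        ])
        shape, scale = priors["mu_A"][jb]
        delta = (new_ll.sum() - cur_ll.sum()
                 + _gamma_logprior(new, shape, scale)
                 - _gamma_logprior(old, shape, scale)
                 + math.log(new / old))
        accept[name][1] += 1
        if math.log(rng.random()) < delta:
            params.mu_A[jb] = new
            muA = muA_new
            cur_ll[:] = new_ll
            accept[name][0] += 1

    for r in range(R):
        name = "mu_B"
        old = params.mu_B[r]
        new = old * math.exp(scales[name] * rng.standard_normal())
        new_ll = _roi_loglik(w[r], logw[r], counts_all[r], new, muA, gain)
        shape, scale = priors["mu_B"][r]
        delta = (new_ll - cur_ll[r]
                 + _gamma_logprior(new, shape, scale)
                 - _gamma_logprior(old, shape, scale)
                 + math.log(new / old))
        accept[name][1] += 1
        if math.log(rng.random()) < delta:
            params.mu_B[r] = new
            cur_ll[r] = new_ll
            accept[name][0] += 1


# ---------------------------------------------------------------------------
# initialisation

def initialize(
    traces: TraceSet,
    config: InferenceConfig,
    state_model: PhotoStateModel,
):
    """Data-driven starting point for the Gibbs chain.

    Backgrounds from the trailing 5% of frames; a single-fluorophore
    brightness unit from the last clear step above background; loads all
    on, with a ruler-style count guess determining how many chains start
    bright-until-apparent-bleach (the rest idle and bleach at the end).
    """
    w = clamp_readouts(traces.w)
    R, N = w.shape
    G = traces.gain
    K = config.k_loads
    S = state_model.S
    b = state_model.bleached_index
    bright0 = state_model.bright_states[0]
    has_dark = any(m < 0 for m in state_model.bright_map[:-1])
    dark0 = 0 if has_dark else bright0

    tail = max(1, N // 20)
    mu_B = np.maximum(w[:, -tail:].mean(axis=1) / G, 1.0)
    bg_adu = mu_B * G
    sd_adu = np.sqrt(2.0 * mu_B) * G

    # single-fluorophore unit: median magnitude of significant downward
    # steps in a smoothed trace (bleach and blink-off events share it);
    # steps count only if they beat 4x the local shot-noise level. The
    # shortest lag that still finds steps is preferred - longer lags merge
    # consecutive bleaches into double-height steps - and drops are pooled
    # across ROIs because the unit brightness is global.
    from scipy.ndimage import uniform_filter1d

    def _drops(w_r, lag):
        sm = uniform_filter1d(w_r, lag, mode="nearest") / G
        d = sm[lag:] - sm[:-lag]
        local_sd = np.sqrt(2.0 * np.maximum(sm[:-lag], 1.0) / lag)
        out, i = [], 0
        while i < d.size:
            if d[i] < -4.0 * local_sd[i]:
                j = i
                while j < d.size and d[j] < -4.0 * local_sd[j]:
                    j += 1
                out.append(-d[i:j].min())
                i = j
            else:
                i += 1
        return out

    t_bleach = np.zeros(R, dtype=int)
    units = []
    for r in range(R):
        above = np.flatnonzero(w[r] > bg_adu[r] + 3.0 * sd_adu[r])
        t_bleach[r] = int(above[-1]) if above.size else 0
        for lag in (5, 12, 25):
            if 3 * lag > N:
                continue
            found = _drops(w[r], lag)
            if len(found) >= 2 or (found and lag >= 25):
                units.extend(found)
                break
    unit = float(np.median(units)) if units else 0.2 * float(mu_B.mean())
    unit = max(unit, 0.05 * float(mu_B.mean()))

    early = w[:, : min(10, N)].mean(axis=1)
    guess = np.clip(np.round((early - bg_adu) / (unit * G)), 0, K).astype(int)

    nb = state_model.n_bright
    if nb == 2:
        mu_A = np.array([1.1 * unit, 0.9 * unit])
    else:
        mu_A = np.array([unit])

    kin = default_kinetics(state_model, N)
    params = build_params(
        state_model, mu_A, mu_B, G,
        dark_start_fraction=0.2 if has_dark else 0.0, **kin,
    )

    loads = np.ones((R, K), dtype=np.uint8)
    trajs = np.full((R, K, N), b, dtype=np.int8)
    for r in range(R):
        stop = int(np.clip(t_bleach[r], 1, N - 1))
        for k in range(K):
            if k < guess[r]:
                trajs[r, k, :stop] = bright0
            elif has_dark:
                # minimal-footprint valid path: idle, one bright frame, bleach
                trajs[r, k, : N - 1] = dark0
                trajs[r, k, N - 2] = bright0
            else:
                trajs[r, k, 0] = bright0
    latent = LatentConfiguration(loads, trajs, config.gamma)
    priors = {
        "mu_A": [(config.brightness_prior_shape,
                  m / config.brightness_prior_shape) for m in mu_A],
        "mu_B": [(config.brightness_prior_shape,
                  m / config.brightness_prior_shape) for m in mu_B],
        "mh_scales": {
            **{f"mu_A{j + 1}": config.mh_scale for j in range(nb)},
            "mu_B": config.mh_scale_background,
        },
    }
    return latent, params, priors


# ---------------------------------------------------------------------------
# main loop

def _log_posterior(latent, params, state_model, config, cur_ll, priors):
    """Log joint of loaded trajectories, loads and parameters (up to consts)."""
    S = state_model.S
    q = load_prior_prob(config.gamma, latent.K)
    n_on = int(latent.loads.sum())
    n_off = latent.loads.size - n_on
    lp = cur_ll.sum() if config.likelihood_on else 0.0
    lp += n_on * math.log(q) + (n_off * math.log1p(-q) if q < 1 else 0.0)
    trans, init = _pooled_counts(latent, S)
    with np.errstate(divide="ignore"):
        logpi = np.where(trans > 0, np.log(np.maximum(params.pi, 1e-300)), 0.0)
        lp += float((trans * logpi).sum())
        logpi0 = np.where(init > 0, np.log(np.maximum(params.pi0, 1e-300)), 0.0)
        lp += float((init * logpi0).sum())
    for jb, m in enumerate(params.mu_A):
        lp += _gamma_logprior(m, *priors["mu_A"][jb])
    for r, m in enumerate(params.mu_B):
        lp += _gamma_logprior(m, *priors["mu_B"][r])
    return lp


def run_gibbs(
    traces: TraceSet,
    config: InferenceConfig,
    state_model: Optional[PhotoStateModel] = None,
    init: Optional[tuple] = None,
    progress: bool = False,
) -> PosteriorDraws:
    """Run the full Gibbs sampler and collect post-burn-in draws."""
    if state_model is None:
        state_model = PhotoStateModel.four_state()
    if init is None:
        latent, params, priors = initialize(traces, config, state_model)
    else:
        latent, params, priors = init
    params.validate(state_model)

    R, N = traces.w.shape
    K = config.k_loads
    nb = state_model.n_bright
    S = state_model.S

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(R + 2)
    roi_rngs = [np.random.default_rng(c) for c in children[:R]]
    kin_rng = np.random.default_rng(children[R])
    par_rng = np.random.default_rng(children[R + 1])

    w = clamp_readouts(traces.w)
    logw = np.log(w)

    n_keep = config.n_sweeps - config.n_burn
    out = PosteriorDraws(
        counts=np.zeros((n_keep, R), dtype=np.int32),
        loads=np.zeros((n_keep, R, K), dtype=np.uint8),
        mu_A=np.zeros((n_keep, nb)),
        mu_B=np.zeros((n_keep, R)),
        pi=np.zeros((n_keep, S, S)),
        pi0=np.zeros((n_keep, S)),
        log_posterior=np.zeros(n_keep),
        sweep_index=np.zeros(n_keep, dtype=int),
        traj_sweeps=[], traj_draws=[],
        best={"log_posterior": -np.inf},
        accept_rates={},
        config=config, state_model=state_model,
        final_latent=latent,
    )
    accept = {f"mu_A{j + 1}": [0, 0] for j in range(nb)}
    accept["mu_B"] = [0, 0]
    window = {k: (0, 0) for k in accept}
    adapt_snap = {k: (0, 0) for k in accept}
    if "mh_scales" not in priors:
        priors["mh_scales"] = {
            **{f"mu_A{j + 1}": config.mh_scale for j in range(nb)},
            "mu_B": config.mh_scale_background,
        }

    cur_ll = np.zeros(R)
    kept = 0
    for sweep in range(config.n_sweeps):
        counts_all = sweep_states(
            traces, latent, params, config, state_model, roi_rngs
        )
        if config.sample_params:
            params.pi, params.pi0 = sample_kinetics(
                latent, state_model, config, kin_rng
            )
        muA = _mu_a2(params, nb)
        for r in range(R):
            cur_ll[r] = _roi_loglik(w[r], logw[r], counts_all[r],
                                    params.mu_B[r], muA, params.gain)
        if config.sample_params and config.likelihood_on:
            sample_brightness(traces, counts_all, params, config,
                              state_model, par_rng, priors, accept,
                              cur_ll, logw, w)
        lp = _log_posterior(latent, params, state_model, config, cur_ll,
                            priors)
        if not np.isfinite(lp):
            err = RuntimeError(
                f"non-finite log-posterior at sweep {sweep}; aborting"
            )
            err.last_good = {"params": params.copy(), "sweep": sweep,
                             "counts": latent.counts}
            raise err

        # burn-in proposal adaptation: nudge each log step toward ~30%
        # acceptance every 25 sweeps, frozen once retention starts
        if sweep < config.n_burn and (sweep + 1) % 25 == 0:
            for name, (acc, tot) in accept.items():
                a0, t0 = adapt_snap[name]
                if tot > t0:
                    rate = (acc - a0) / (tot - t0)
                    s = priors["mh_scales"][name]
                    s *= math.exp(0.6 * (rate - 0.3))
                    priors["mh_scales"][name] = min(max(s, 1e-4), 0.5)
                adapt_snap[name] = (acc, tot)

        if (sweep + 1) % 100 == 0:
            for name, (acc, tot) in accept.items():
                acc0, tot0 = window[name]
                if tot - tot0 >= 50 and acc == acc0:
                    logger.warning(
                        "no accepted %s proposals in the last window", name
                    )
                window[name] = (acc, tot)
            if progress:
                logger.info("sweep %d/%d log-posterior %.1f counts %s",
                            sweep + 1, config.n_sweeps, lp,
                            latent.counts.tolist())

        if sweep >= config.n_burn:
            out.counts[kept] = latent.counts
            out.loads[kept] = latent.loads
            out.mu_A[kept] = params.mu_A
            out.mu_B[kept] = params.mu_B
            out.pi[kept] = params.pi
            out.pi0[kept] = params.pi0
            out.log_posterior[kept] = lp
            out.sweep_index[kept] = sweep
            if kept % config.thin_traj == 0:
                out.traj_sweeps.append(sweep)
                out.traj_draws.append(latent.trajs.copy())
            if lp > out.best["log_posterior"]:
                out.best = {
                    "log_posterior": lp, "sweep": sweep,
                    "trajs": latent.trajs.copy(),
                    "loads": latent.loads.copy(),
                    "params": params.copy(),
                }
            kept += 1

    out.accept_rates = {
        k: (v[0] / v[1] if v[1] else float("nan")) for k, v in accept.items()
    }
    return out
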
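"""Brute-force enumeration oracle for tiny load/trajectory posteriors.

Independent of the sampler internals: trajectories are enumerated
exhaustively, priors multiplied out term by term, and the emission
likelihood evaluated with scipy's gamma density.
"""

import itertools
import math

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from blinkcount import load_prior_prob


def enumerate_joint(w, params, model, gamma, k_total, j, likelihood=True):
    """Exact posterior over (loads, trajectories) for J chains.

    Returns (config probs, per-frame state marginals of chain 0). Only
    trajectories ending bleached and traversing allowed transitions enter
    the sum.
    """
    N = len(w)
    S = model.S
    bright = model.state_brightness(params.mu_A)
    q = load_prior_prob(gamma, k_total)

    trajs = []
    logpri = []
    for seq in itertools.product(range(S), repeat=N):
        if seq[-1] != model.bleached_index:
            continue
        ok = all(model.allowed[a, b] for a, b in zip(seq, seq[1:]))
        if not ok or params.pi0[seq[0]] == 0.0:
            continue
        lp = math.log(params.pi0[seq[0]])
        for a, b in zip(seq, seq[1:]):
            lp += math.log(params.pi[a, b])
        trajs.append(seq)
        logpri.append(lp)
    trajs = np.array(trajs)
    logpri = np.array(logpri)

    configs = list(itertools.product([0, 1], repeat=j))
    logpost = {}
    for cfg in configs:
        lp_cfg = sum(math.log(q) if b else math.log(1 - q) for b in cfg)
        block = np.zeros((len(trajs),) * j)
        for idx in itertools.product(range(len(trajs)), repeat=j):
            lp = lp_cfg + sum(logpri[i] for i in idx)
            if likelihood:
                mu = params.mu_B[0] + sum(
                    b * bright[trajs[i]] for b, i in zip(cfg, idx)
                )
                lp += stats.gamma.logpdf(w, a=mu / 2,
                                         scale=2 * params.gain).sum()
            block[idx] = lp
        logpost[cfg] = block
    norm = logsumexp([logsumexp(b) for b in logpost.values()])
    cfg_probs = {c: math.exp(logsumexp(b) - norm) for c, b in logpost.items()}
    marg = np.zeros((N, S))
    for cfg, block in logpost.items():
        p = np.exp(block - norm)
        p0 = p.sum(axis=tuple(range(1, j))) if j > 1 else p
        for i, t in enumerate(trajs):
            marg[np.arange(N), t] += p0[i]
    return cfg_probs, marg
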
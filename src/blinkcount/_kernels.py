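"""Numba kernels for forward-filter backward-sampling over load pairs.

Filtering uses per-frame max-subtraction on the log-emission levels
followed by scaled linear-domain recursion with per-frame normalisation
(accumulating the log-normaliser), which guards against underflow at a
fraction of the cost of per-frame logsumexp.

Emission log-densities drop per-frame constants that are common to every
brightness level (they cancel in the max-shift): with x_n = ln w_n -
ln 2G, the level-dependent part of ln Gamma(w_n; mu/2, 2G) is
0.5*mu*x_n - lgamma(mu/2). lgamma values are cached per (bright-state
count) lattice point, which is what makes the sweep affordable.
"""

import math

import numpy as np
from numba import njit

NEG_INF = -1.0e300


@njit(cache=True, nogil=True, fastmath=True)
def _prior_filter(pi0, pi, alpha):
    """Flat-emission filter: alpha[n] is the prior state marginal."""
    N, S = alpha.shape
    logc = 0.0
    tot = 0.0
    for s in range(S):
        alpha[0, s] = pi0[s]
        tot += pi0[s]
    for s in range(S):
        alpha[0, s] /= tot
    logc += math.log(tot)
    for n in range(1, N):
        tot = 0.0
        for j in range(S):
            acc = 0.0
            for i in range(S):
                acc += alpha[n - 1, i] * pi[i, j]
            alpha[n, j] = acc
            tot += acc
        for j in range(S):
            alpha[n, j] /= tot
        logc += math.log(tot)
    return logc


@njit(cache=True, nogil=True, fastmath=True)
def _filter_single(pi0, pi, em, sl, alpha):
    """One loaded chain against emissions; returns (log-normaliser, fail frame)."""
    N, S = alpha.shape
    logc = 0.0
    tot = 0.0
    for s in range(S):
        v = pi0[s] * em[0, sl[s]]
        alpha[0, s] = v
        tot += v
    if not tot > 0.0:
        return NEG_INF, 0
    for s in range(S):
        alpha[0, s] /= tot
    logc += math.log(tot)
    for n in range(1, N):
        tot = 0.0
        for j in range(S):
            acc = 0.0
            for i in range(S):
                acc += alpha[n - 1, i] * pi[i, j]
            v = acc * em[n, sl[j]]
            alpha[n, j] = v
            tot += v
        if not tot > 0.0:
            return NEG_INF, n
        for j in range(S):
            alpha[n, j] /= tot
        logc += math.log(tot)
    return logc, -1


@njit(cache=True, nogil=True, fastmath=True)
def _filter_pair(pi0, pi, em, pl, alpha):
    """Two loaded chains on the joint S*S space; factorised transition."""
    N = em.shape[0]
    S = pi.shape[0]
    beta = np.empty((S, S))
    tot = 0.0
    for s1 in range(S):
        for s2 in range(S):
            v = pi0[s1] * pi0[s2] * em[0, pl[s1, s2]]
            alpha[0, s1, s2] = v
            tot += v
    if not tot > 0.0:
        return NEG_INF, 0
    inv = 1.0 / tot
    for s1 in range(S):
        for s2 in range(S):
            alpha[0, s1, s2] *= inv
    logc = math.log(tot)
    for n in range(1, N):
        for j1 in range(S):
            for i2 in range(S):
                acc = 0.0
                for i1 in range(S):
                    acc += alpha[n - 1, i1, i2] * pi[i1, j1]
                beta[j1, i2] = acc
        tot = 0.0
        for j1 in range(S):
            for j2 in range(S):
                acc = 0.0
                for i2 in range(S):
                    acc += beta[j1, i2] * pi[i2, j2]
                v = acc * em[n, pl[j1, j2]]
                alpha[n, j1, j2] = v
                tot += v
        if not tot > 0.0:
            return NEG_INF, n
        inv = 1.0 / tot
        for j1 in range(S):
            for j2 in range(S):
                alpha[n, j1, j2] *= inv
        logc += math.log(tot)
    return logc, -1


@njit(cache=True, nogil=True)
def _backward_single(alpha, pi, u, out, final_state):
    """Backward-sample one trajectory; final_state<0 samples the last frame."""
    N, S = alpha.shape
    if final_state >= 0:
        s = final_state
    else:
        r = u[N - 1]
        c = 0.0
        s = 0
        for i in range(S):
            if alpha[N - 1, i] > 0.0:
                s = i
        cpick = -1
        for i in range(S):
            c += alpha[N - 1, i]
            if r < c:
                cpick = i
                break
        if cpick >= 0:
            s = cpick
    out[N - 1] = s
    for n in range(N - 2, -1, -1):
        tot = 0.0
        last = 0
        for i in range(S):
            wgt = alpha[n, i] * pi[i, s]
            tot += wgt
            if wgt > 0.0:
                last = i
        r = u[n] * tot
        c = 0.0
        nxt = last
        for i in range(S):
            c += alpha[n, i] * pi[i, s]
            if r < c:
                nxt = i
                break
        out[n] = nxt
        s = nxt


@njit(cache=True, nogil=True)
def _backward_pair(alpha, pi, u, out1, out2, final_state):
    """Backward-sample a joint pair trajectory from the S*S filter."""
    N = alpha.shape[0]
    S = pi.shape[0]
    if final_state >= 0:
        s1 = final_state
        s2 = final_state
    else:
        r = u[N - 1]
        c = 0.0
        s1 = 0
        s2 = 0
        done = False
        for i1 in range(S):
            for i2 in range(S):
                if alpha[N - 1, i1, i2] > 0.0:
                    s1 = i1
                    s2 = i2
        for i1 in range(S):
            if done:
                break
            for i2 in range(S):
                c += alpha[N - 1, i1, i2]
                if r < c:
                    s1 = i1
                    s2 = i2
                    done = True
                    break
    out1[N - 1] = s1
    out2[N - 1] = s2
    for n in range(N - 2, -1, -1):
        tot = 0.0
        l1 = 0
        l2 = 0
        for i1 in range(S):
            for i2 in range(S):
                wgt = alpha[n, i1, i2] * pi[i1, s1] * pi[i2, s2]
                tot += wgt
                if wgt > 0.0:
                    l1 = i1
                    l2 = i2
        r = u[n] * tot
        c = 0.0
        n1 = l1
        n2 = l2
        done = False
        for i1 in range(S):
            if done:
                break
            for i2 in range(S):
                c += alpha[n, i1, i2] * pi[i1, s1] * pi[i2, s2]
                if r < c:
                    n1 = i1
                    n2 = i2
                    done = True
                    break
        out1[n] = n1
        out2[n] = n2
        s1 = n1
        s2 = n2


@njit(cache=True, nogil=True)
def sweep_states_roi(
    x,                # (N,) ln w_n - ln 2G, readouts pre-clamped
    pi0, pi,          # (S,), (S, S)
    mu_B,             # scalar background photons/frame for this ROI
    muA,              # (2,) bright brightnesses; muA[1] unused when nb == 1
    nb,               # number of bright states (1 or 2)
    sc,               # (S,) bright index per state, -1 for dark/bleached
    lev,              # (L, 2) per level: counts of bright1/bright2 added
    pl, sl,           # (S, S) and (S,) level index tables
    q_on,             # Bernoulli load prior gamma / (K + gamma - 1)
    loads, trajs,     # (K,) uint8 and (K, N) int8, updated in place
    groups,           # (G, 2) chain indices per FFBS group, -1 pad
    base_counts,      # (N, 2) int32 bright counts from chains outside `loads`
    cache_dim,        # lgamma cache side length (> max bright count + 2)
    u_conf, u_traj,   # (G,) and (K, N) uniforms
    likelihood_on, constrain_final,
):
    """One Gibbs pass over all load groups of a single ROI.

    Returns (status, counts): status 0 on success, or 1 + frame index of
    the first frame at which every load configuration had zero filter
    mass; counts is the (N, 2) bright-state occupancy of loaded chains
    after the pass (used by the brightness updates).
    """
    N = x.shape[0]
    S = pi.shape[0]
    K = loads.shape[0]
    L = lev.shape[0]
    G = groups.shape[0]
    bleach = S - 1

    counts = base_counts.copy()
    for k in range(K):
        if loads[k] == 1:
            for n in range(N):
                c = sc[trajs[k, n]]
                if c >= 0:
                    counts[n, c] += 1

    lgcache = np.full(cache_dim * cache_dim, np.nan)
    em = np.empty((N, L))
    emlog = np.empty(L)
    alpha1 = np.empty((N, S))
    alpha2 = np.empty((N, S, S))
    alpha_prior = np.empty((N, S))

    logc_prior = _prior_filter(pi0, pi, alpha_prior)
    if constrain_final:
        tailp = alpha_prior[N - 1, bleach]
        logCp = logc_prior + math.log(tailp) if tailp > 0.0 else NEG_INF
    else:
        logCp = 0.0

    lq = math.log(q_on) if q_on > 0.0 else NEG_INF
    lmq = math.log(1.0 - q_on) if q_on < 1.0 else NEG_INF

    final1 = bleach if constrain_final else -1

    for g in range(G):
        k1 = groups[g, 0]
        k2 = groups[g, 1]
        pair = k2 >= 0

        if loads[k1] == 1:
            for n in range(N):
                c = sc[trajs[k1, n]]
                if c >= 0:
                    counts[n, c] -= 1
        if pair and loads[k2] == 1:
            for n in range(N):
                c = sc[trajs[k2, n]]
                if c >= 0:
                    counts[n, c] -= 1

        e0 = 0.0
        if likelihood_on:
            for n in range(N):
                mmax = -1.0e308
                for l in range(L):
                    a = counts[n, 0] + lev[l, 0]
                    b = counts[n, 1] + lev[l, 1]
                    mu = mu_B + a * muA[0] + b * muA[1]
                    idx = a * cache_dim + b
                    lg = lgcache[idx]
                    if lg != lg:
                        lg = math.lgamma(0.5 * mu)
                        lgcache[idx] = lg
                    v = 0.5 * mu * x[n] - lg
                    emlog[l] = v
                    if v > mmax:
                        mmax = v
                for l in range(L):
                    em[n, l] = math.exp(emlog[l] - mmax)
                e0 += emlog[0] - mmax
        else:
            for n in range(N):
                for l in range(L):
                    em[n, l] = 1.0

        logc1, fail1 = _filter_single(pi0, pi, em, sl, alpha1)
        if logc1 <= NEG_INF:
            logF1 = NEG_INF
        elif constrain_final:
            tail = alpha1[N - 1, bleach]
            logF1 = logc1 + math.log(tail) if tail > 0.0 else NEG_INF
        else:
            logF1 = logc1

        if pair:
            logc2, fail2 = _filter_pair(pi0, pi, em, pl, alpha2)
            if logc2 <= NEG_INF:
                logF11 = NEG_INF
            elif constrain_final:
                tail = alpha2[N - 1, bleach, bleach]
                logF11 = logc2 + math.log(tail) if tail > 0.0 else NEG_INF
            else:
                logF11 = logc2

            w0 = 2.0 * lmq + 2.0 * logCp + e0
            w1 = lq + lmq + logCp + logF1
            w2 = w1
            w3 = 2.0 * lq + logF11
            mmax = max(max(w0, w1), max(w2, w3))
            if mmax <= NEG_INF:
                ff = fail2 if fail2 >= 0 else (fail1 if fail1 >= 0 else 0)
                return 1 + ff, counts
            p0 = math.exp(w0 - mmax)
            p1 = math.exp(w1 - mmax)
            p2 = math.exp(w2 - mmax)
            p3 = math.exp(w3 - mmax)
            tot = p0 + p1 + p2 + p3
            r = u_conf[g] * tot
            if r < p0:
                cfg = 0
            elif r < p0 + p1:
                cfg = 1
            elif r < p0 + p1 + p2:
                cfg = 2
            else:
                cfg = 3

            if cfg == 3:
                loads[k1] = 1
                loads[k2] = 1
                _backward_pair(alpha2, pi, u_traj[k1], trajs[k1], trajs[k2],
                               final1)
            elif cfg == 1:
                loads[k1] = 1
                loads[k2] = 0
                _backward_single(alpha1, pi, u_traj[k1], trajs[k1], final1)
                _backward_single(alpha_prior, pi, u_traj[k2], trajs[k2],
                                 final1)
            elif cfg == 2:
                loads[k1] = 0
                loads[k2] = 1
                _backward_single(alpha_prior, pi, u_traj[k1], trajs[k1],
                                 final1)
                _backward_single(alpha1, pi, u_traj[k2], trajs[k2], final1)
            else:
                loads[k1] = 0
                loads[k2] = 0
                _backward_single(alpha_prior, pi, u_traj[k1], trajs[k1],
                                 final1)
                _backward_single(alpha_prior, pi, u_traj[k2], trajs[k2],
                                 final1)
        else:
            w0 = lmq + logCp + e0
            w1 = lq + logF1
            mmax = max(w0, w1)
            if mmax <= NEG_INF:
                ff = fail1 if fail1 >= 0 else 0
                return 1 + ff, counts
            p0 = math.exp(w0 - mmax)
            p1 = math.exp(w1 - mmax)
            cfg = 1 if u_conf[g] * (p0 + p1) >= p0 else 0
            if cfg == 1:
                loads[k1] = 1
                _backward_single(alpha1, pi, u_traj[k1], trajs[k1], final1)
            else:
                loads[k1] = 0
                _backward_single(alpha_prior, pi, u_traj[k1], trajs[k1],
                                 final1)

        if loads[k1] == 1:
            for n in range(N):
                c = sc[trajs[k1, n]]
                if c >= 0:
                    counts[n, c] += 1
        if pair and loads[k2] == 1:
            for n in range(N):
                c = sc[trajs[k2, n]]
                if c >= 0:
                    counts[n, c] += 1

    return 0, counts
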
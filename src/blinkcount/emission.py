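"""EMCCD emission model and Beta-Bernoulli load prior primitives.

The camera readout of an ROI whose expected photon count for the frame is
``mu`` is modelled as ``w ~ Gamma(shape=mu/2, scale=2*G)`` with gain ``G``
in ADU per photon-equivalent. This reproduces the electron-multiplication
excess noise: mean ``mu*G`` and variance ``2*mu*G**2``, i.e. twice the
Poisson-limited variance.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats

from .states import ModelParams, PhotoStateModel

__all__ = [
    "ADU_FLOOR",
    "clamp_readouts",
    "mean_brightness",
    "emission_logdensity",
    "readout_moments",
    "load_prior_prob",
]

# Integer-quantised real traces can contain exact zeros; the gamma support
# is (0, inf), so readouts below this floor are clamped before likelihood
# evaluation.
ADU_FLOOR = 0.5


def clamp_readouts(w: np.ndarray, floor: float = ADU_FLOOR) -> np.ndarray:
    """Clamp readouts to ``floor`` so they lie in the gamma support."""
    return np.maximum(np.asarray(w, dtype=float), floor)


def mean_brightness(
    states: Sequence[int],
    loads: Sequence[int],
    params: ModelParams,
    state_model: PhotoStateModel,
    roi: int = 0,
) -> float:
    """Mean ROI photon count for one frame given the fluorophore states.

    Returns ``mu_B[roi] + sum_k loads[k] * brightness(states[k])``: the
    background plus one bright-state brightness per *loaded* fluorophore
    currently in a bright state. Loads gate contributions, so a switched-off
    (virtual) fluorophore adds nothing regardless of its nominal state.
    """
    states = np.asarray(states, dtype=int)
    loads = np.asarray(loads)
    if states.shape != loads.shape:
        raise ValueError("states and loads must have equal length")
    bright = state_model.state_brightness(params.mu_A)
    return float(params.mu_B[roi] + np.sum(loads * bright[states]))


def emission_logdensity(w, mu, gain):
    """Log gamma density of the readout: ``Gamma(mu/2, 2*gain)`` at ``w``.

    ``w <= 0`` evaluates to ``-inf`` (support boundary); ``mu`` must be
    positive — a positive background guarantees this in the full model.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mu must be positive")
    if gain <= 0:
        raise ValueError("gain must be positive")
    w = np.asarray(w, dtype=float)
    out = np.where(
        w > 0,
        stats.gamma.logpdf(np.maximum(w, np.finfo(float).tiny),
                           a=mu / 2.0, scale=2.0 * gain),
        -np.inf,
    )
    return float(out) if out.ndim == 0 else out


def readout_moments(mu: float, gain: float):
    """Mean and standard deviation of the readout in ADU.

    Mean is ``mu*gain``; the variance carries the excess noise factor of
    two, ``2*mu*gain**2``.
    """
    if mu <= 0 or gain <= 0:
        raise ValueError("mu and gain must be positive")
    mean = stats.gamma.mean(a=mu / 2.0, scale=2.0 * gain)
    sd = stats.gamma.std(a=mu / 2.0, scale=2.0 * gain)
    return float(mean), float(sd)


def load_prior_prob(gamma: float, K: int) -> float:
    """Weak-limit Beta-Bernoulli load prior: ``gamma / (K + gamma - 1)``.

    As the truncation K grows at fixed concentration gamma the per-load
    probability vanishes while the expected number of active loads stays
    finite, approaching the infinite Beta-Bernoulli process.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if K < 1:
        raise ValueError("K must be at least 1")
    return gamma / (K + gamma - 1.0)
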
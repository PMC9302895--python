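"""Photo-state spaces, model parameters, traces and latent configurations.

A fluorophore occupies one photo-state per frame: dark (non-emitting but
recoverable), one or two active (bright) states, and an absorbing
photobleached state. The state space is deliberately small and ordered so
the bleached state is always last, which makes the "trajectories end
bleached" constraint a single index check everywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PhotoStateModel",
    "ModelParams",
    "TraceSet",
    "GroundTruth",
    "LatentConfiguration",
]


@dataclass(frozen=True)
class PhotoStateModel:
    """Discrete photo-state space with an absorbing bleached state.

    Parameters
    ----------
    labels : tuple of str
        State names, bleached state last.
    bright_map : tuple of int
        Per state, the index of the bright-brightness parameter it draws
        (``mu_A[bright_map[s]]``), or ``-1`` for non-emitting states
        (dark, bleached).
    allowed : ndarray of bool, shape (S, S)
        Permitted transitions. The bleached row permits only
        self-transition; dark states may never bleach directly.
    """

    labels: tuple
    bright_map: tuple
    allowed: np.ndarray

    def __post_init__(self):
        allowed = np.asarray(self.allowed, dtype=bool)
        object.__setattr__(self, "allowed", allowed)
        S = len(self.labels)
        if allowed.shape != (S, S):
            raise ValueError("allowed mask must be S x S")
        if S not in (2, 3, 4):
            raise ValueError("supported state spaces have 2-4 states")
        if len(self.bright_map) != S:
            raise ValueError("bright_map must have one entry per state")
        b = self.bleached_index
        # exactly one absorbing state, and it is the last one
        absorbing = [
            i for i in range(S)
            if allowed[i, i] and not allowed[i, np.arange(S) != i].any()
        ]
        if absorbing != [b]:
            raise ValueError("exactly one absorbing (bleached) state, last")
        if self.bright_map[b] != -1:
            raise ValueError("bleached state cannot be bright")
        for i in range(S):
            if i != b and self.bright_map[i] < 0 and allowed[i, b]:
                raise ValueError("dark states may not bleach directly")
        if not any(m >= 0 for m in self.bright_map):
            raise ValueError("at least one bright state required")

    # -- structure ---------------------------------------------------------

    @property
    def S(self) -> int:
        return len(self.labels)

    @property
    def bleached_index(self) -> int:
        return self.S - 1

    @property
    def n_bright(self) -> int:
        return int(max(self.bright_map) + 1)

    @property
    def bright_states(self) -> tuple:
        return tuple(i for i, m in enumerate(self.bright_map) if m >= 0)

    def state_brightness(self, mu_A: Sequence[float]) -> np.ndarray:
        """Per-state mean photons per frame: 0 for dark/bleached."""
        mu_A = np.asarray(mu_A, dtype=float)
        if mu_A.shape != (self.n_bright,):
            raise ValueError("mu_A must supply one brightness per bright state")
        if np.any(mu_A <= 0):
            raise ValueError("bright-state brightness must be positive")
        out = np.zeros(self.S)
        for s, m in enumerate(self.bright_map):
            if m >= 0:
                out[s] = mu_A[m]
        return out

    # -- standard spaces ---------------------------------------------------

    @classmethod
    def three_state(cls) -> "PhotoStateModel":
        """Dark / active / photobleached (the default kinetic scheme)."""
        allowed = np.array(
            [
                [1, 1, 0],  # dark: stay or recover to bright
                [1, 1, 1],  # bright: blink off, stay, or bleach
                [0, 0, 1],  # bleached: absorbing
            ],
            dtype=bool,
        )
        return cls(("dark", "bright", "bleached"), (-1, 0, -1), allowed)

    @classmethod
    def four_state(cls, interconvert: bool = True) -> "PhotoStateModel":
        """Dark / two active states / photobleached (ATTO647N-like dyes).

        ``interconvert=False`` forbids direct bright1<->bright2 hops.
        """
        i = 1 if interconvert else 0
        allowed = np.array(
            [
                [1, 1, 1, 0],
                [1, 1, i, 1],
                [1, i, 1, 1],
                [0, 0, 0, 1],
            ],
            dtype=bool,
        )
        return cls(
            ("dark", "bright1", "bright2", "bleached"), (-1, 0, 1, -1), allowed
        )

    @classmethod
    def two_state(cls) -> "PhotoStateModel":
        """Bright / photobleached: the restricted comparison model (no dark)."""
        allowed = np.array([[1, 1], [0, 1]], dtype=bool)
        return cls(("bright", "bleached"), (0, -1), allowed)


@dataclass
class ModelParams:
    """Kinetic and brightness parameters of the forward model.

    ``pi`` is the per-frame transition matrix (row-stochastic, structural
    zeros on forbidden transitions), ``pi0`` the initial-state distribution
    (zero mass on bleached), ``mu_A`` the bright-state mean photon counts
    per frame, ``mu_B`` the per-ROI background mean photon counts, and
    ``gain`` the EMCCD gain in ADU per photon-equivalent.
    """

    pi0: np.ndarray
    pi: np.ndarray
    mu_A: np.ndarray
    mu_B: np.ndarray
    gain: float

    def __post_init__(self):
        self.pi0 = np.asarray(self.pi0, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        self.mu_A = np.atleast_1d(np.asarray(self.mu_A, dtype=float))
        self.mu_B = np.atleast_1d(np.asarray(self.mu_B, dtype=float))
        self.gain = float(self.gain)

    def validate(self, model: PhotoStateModel) -> None:
        S = model.S
        if self.pi.shape != (S, S) or self.pi0.shape != (S,):
            raise ValueError("pi / pi0 shapes do not match the state model")
        if not np.allclose(self.pi.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("pi rows must sum to 1")
        if np.any(self.pi[~model.allowed] != 0.0):
            raise ValueError("pi must be zero on forbidden transitions")
        if np.any(self.pi < 0):
            raise ValueError("pi must be nonnegative")
        if not np.isclose(self.pi0.sum(), 1.0, atol=1e-10):
            raise ValueError("pi0 must sum to 1")
        if self.pi0[model.bleached_index] != 0.0:
            raise ValueError("pi0 must put zero mass on the bleached state")
        if np.any(self.pi0 < 0):
            raise ValueError("pi0 must be nonnegative")
        if self.mu_A.shape != (model.n_bright,) or np.any(self.mu_A <= 0):
            raise ValueError("mu_A must be positive, one per bright state")
        if np.any(self.mu_B < 0):
            raise ValueError("mu_B must be nonnegative")
        if self.gain <= 0:
            raise ValueError("gain must be positive")

    def copy(self) -> "ModelParams":
        return ModelParams(
            self.pi0.copy(), self.pi.copy(), self.mu_A.copy(),
            self.mu_B.copy(), self.gain,
        )


@dataclass
class GroundTruth:
    """Simulation ground truth attached to a :class:`TraceSet`."""

    counts: np.ndarray  # (R,) true fluorophore count per ROI
    params: ModelParams
    state_model: PhotoStateModel
    trajectories: Optional[list] = None  # per ROI: (K_r, N) int8 state array

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)


@dataclass
class TraceSet:
    """Observed ADU brightness traces for R ROIs over N frames.

    ``w`` has shape (R, N). All ROIs share the frame period and camera
    gain; readouts must be nonnegative.
    """

    w: np.ndarray
    frame_period: float
    gain: float
    ground_truth: Optional[GroundTruth] = None
    roi_names: Optional[list] = None

    def __post_init__(self):
        self.w = np.atleast_2d(np.asarray(self.w, dtype=float))
        if np.any(self.w < 0):
            raise ValueError("ADU readouts must be nonnegative")
        if self.frame_period <= 0 or self.gain <= 0:
            raise ValueError("frame_period and gain must be positive")
        if self.roi_names is None:
            self.roi_names = [f"roi_{r}" for r in range(self.R)]

    @property
    def R(self) -> int:
        return self.w.shape[0]

    @property
    def N(self) -> int:
        return self.w.shape[1]


@dataclass
class LatentConfiguration:
    """Loads and photo-state trajectories of the K model fluorophores.

    ``loads[r, k]`` flags whether model fluorophore k contributes to ROI r;
    ``trajs[r, k, n]`` is its photo-state at frame n. ``gamma`` is the
    Beta-Bernoulli concentration behind the load prior.
    """

    loads: np.ndarray  # (R, K) uint8
    trajs: np.ndarray  # (R, K, N) int8
    gamma: float

    def __post_init__(self):
        self.loads = np.asarray(self.loads, dtype=np.uint8)
        self.trajs = np.asarray(self.trajs, dtype=np.int8)
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")

    @property
    def K(self) -> int:
        return self.loads.shape[1]

    @property
    def counts(self) -> np.ndarray:
        """Per-ROI fluorophore count B_r = sum_k loads."""
        return self.loads.sum(axis=1).astype(int)

    def validate(self, model: PhotoStateModel) -> None:
        b = model.bleached_index
        if np.any(self.trajs[:, :, -1] != b):
            raise ValueError("every trajectory must end bleached")
        frm = self.trajs[:, :, :-1]
        to = self.trajs[:, :, 1:]
        if not model.allowed[frm, to].all():
            raise ValueError("trajectory uses a forbidden transition")
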
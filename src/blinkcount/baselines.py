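"""Comparison counting methods: the two-state restricted model and the
fluorescence ruler.

The two-state model is the full Gibbs engine run on a bright/bleached
state space (no dark state, bright start): equivalent to classical
photobleaching step counting with population bookkeeping. It cannot
represent blinking, which is exactly the failure mode the comparisons
probe. The ruler divides background-subtracted initial brightness by a
single-fluorophore calibration unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gibbs import InferenceConfig, PosteriorDraws, run_gibbs
from .states import PhotoStateModel, TraceSet

__all__ = ["RulerCalibration", "ruler_estimate", "two_state_infer"]


@dataclass
class RulerCalibration:
    """Calibration standard for ruler counting.

    ``unit_brightness`` is the ADU contribution of one active fluorophore
    (mu_A * G), ``background_level`` the ADU background (mu_B * G), and
    ``n_initial_frames`` how many frames at the trace start are averaged.
    """

    unit_brightness: float
    background_level: float
    n_initial_frames: int = 10

    def __post_init__(self):
        if self.unit_brightness <= 0:
            raise ValueError("unit_brightness must be positive")
        if self.n_initial_frames < 1:
            raise ValueError("n_initial_frames must be >= 1")

    @classmethod
    def from_ground_truth(cls, traces: TraceSet, roi: int = 0,
                          n_initial_frames: int = 10) -> "RulerCalibration":
        """True calibration from simulation ground truth.

        With several bright states the single-fluorophore unit is the
        initial-state expected brightness: the pi0-weighted mean of the
        bright-state brightnesses (given the fluorophore starts bright).
        """
        gt = traces.ground_truth
        if gt is None:
            raise ValueError("trace set carries no ground truth")
        model = gt.state_model
        bright = list(model.bright_states)
        p = gt.params.pi0[bright]
        if p.sum() <= 0:
            unit_mu = float(gt.params.mu_A.mean())
        else:
            unit_mu = float(np.dot(p / p.sum(), gt.params.mu_A))
        return cls(unit_mu * gt.params.gain,
                   float(gt.params.mu_B[roi]) * gt.params.gain,
                   n_initial_frames)


def ruler_estimate(trace: np.ndarray, calib: RulerCalibration) -> int:
    """Count = round((initial-window mean - background) / unit), floored at 0."""
    trace = np.asarray(trace, dtype=float)
    if trace.shape[0] < calib.n_initial_frames:
        raise ValueError("trace shorter than the calibration window")
    level = trace[: calib.n_initial_frames].mean() - calib.background_level
    return int(max(round(level / calib.unit_brightness), 0))


def two_state_infer(
    traces: TraceSet,
    config: InferenceConfig,
    progress: bool = False,
) -> PosteriorDraws:
    """Run the identical Gibbs engine under the bright/bleached model."""
    return run_gibbs(traces, config, state_model=PhotoStateModel.two_state(),
                     progress=progress)
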
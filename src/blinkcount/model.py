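"""Model / Results front end over the Gibbs engine.

``FluorophoreCountModel`` is built from a :class:`TraceSet` (or a CSV
trace file) and ``fit()`` returns a ``FluorophoreCountResults`` carrying
the posterior draws, per-ROI count estimates with credible intervals,
error metrics against ground truth, and plotting helpers.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .gibbs import InferenceConfig, PosteriorDraws, run_gibbs
from .states import PhotoStateModel, TraceSet
from .summarize import CountSummary, count_posterior, mean_error, \
    trajectory_overlay

__all__ = ["FluorophoreCountModel", "FluorophoreCountResults"]


class FluorophoreCountModel:
    """Bayesian nonparametric fluorophore counter for brightness traces.

    Parameters
    ----------
    traces : TraceSet
        Observed ADU traces with gain and frame-period metadata.
    state_model : PhotoStateModel, optional
        Photo-state space; defaults to dark + two bright + bleached
        (ATTO647N-like). Use ``PhotoStateModel.three_state()`` for a
        single bright state.
    k_loads, gamma, j_joint, **config_kwargs
        Forwarded to :class:`InferenceConfig`.

    Examples
    --------
    >>> from blinkcount import BenchmarkConfig, make_benchmark
    >>> ts = make_benchmark(BenchmarkConfig(n_rois=2, n_frames=500, seed=1))
    >>> res = FluorophoreCountModel(ts, k_loads=40).fit(n_sweeps=200, seed=0)
    >>> res.counts_.shape
    (2,)
    """

    def __init__(
        self,
        traces: TraceSet,
        state_model: Optional[PhotoStateModel] = None,
        **config_kwargs,
    ):
        self.traces = traces
        self.state_model = state_model or PhotoStateModel.four_state()
        self._config_kwargs = config_kwargs

    @classmethod
    def from_csv(cls, path, **kwargs) -> "FluorophoreCountModel":
        """Build from a trace CSV with gain/frame-period sidecar metadata."""
        from .io import read_traces
        return cls(read_traces(path), **kwargs)

    def fit(
        self,
        n_sweeps: Optional[int] = None,
        n_burn: Optional[int] = None,
        seed: Optional[int] = None,
        progress: bool = False,
        **overrides,
    ) -> "FluorophoreCountResults":
        kw = dict(self._config_kwargs)
        kw.update(overrides)
        if n_sweeps is not None:
            kw["n_sweeps"] = n_sweeps
        if n_burn is not None:
            kw["n_burn"] = n_burn
        if seed is not None:
            kw["seed"] = seed
        config = InferenceConfig(**kw)
        draws = run_gibbs(self.traces, config, state_model=self.state_model,
                          progress=progress)
        return FluorophoreCountResults(self, draws)


class FluorophoreCountResults:
    """Posterior inference results of :class:`FluorophoreCountModel`."""

    def __init__(self, model: FluorophoreCountModel, draws: PosteriorDraws):
        self.model = model
        self.draws = draws
        self._summary: Optional[CountSummary] = None

    # -- estimates ---------------------------------------------------------

    @property
    def count_summary(self) -> CountSummary:
        if self._summary is None:
            self._summary = count_posterior(self.draws)
        return self._summary

    @property
    def counts_(self) -> np.ndarray:
        """Posterior-mean fluorophore count per ROI."""
        return self.count_summary.mean

    @property
    def counts_map_(self) -> np.ndarray:
        """Posterior-mode (MAP) integer count per ROI."""
        return self.count_summary.map

    @property
    def mu_A_(self) -> np.ndarray:
        return self.draws.mu_A.mean(axis=0)

    @property
    def mu_B_(self) -> np.ndarray:
        return self.draws.mu_B.mean(axis=0)

    @property
    def pi_(self) -> np.ndarray:
        return self.draws.pi.mean(axis=0)

    @property
    def pi0_(self) -> np.ndarray:
        return self.draws.pi0.mean(axis=0)

    def error_metrics(self, truth: Optional[np.ndarray] = None) -> dict:
        """Counting-error metrics against ground truth (simulation only)."""
        if truth is None:
            gt = self.model.traces.ground_truth
            if gt is None:
                raise ValueError("no ground truth available")
            truth = gt.counts
        return mean_error(self.count_summary, truth)

    def trajectory_overlay(self, roi: int, which: str = "best") -> pd.DataFrame:
        return trajectory_overlay(self.draws, self.model.traces, roi, which)

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        """Readable report: per-ROI counts, brightnesses, kinetics."""
        d = self.draws
        sm = self.model.state_model
        tab = self.count_summary.table
        lines = []
        lines.append("Fluorophore count posterior "
                     f"({d.n_kept} draws, {d.R} ROIs, K={d.config.k_loads}, "
                     f"gamma={d.config.gamma})")
        lines.append("-" * 64)
        lines.append(f"{'ROI':>4} {'mean':>8} {'MAP':>5} {'95% CI':>12}")
        for r, row in tab.iterrows():
            ci = f"[{int(row.ci_low)}, {int(row.ci_high)}]"
            lines.append(f"{r:>4} {row['mean']:>8.2f} {int(row['map']):>5d} "
                         f"{ci:>12}")
        lines.append("-" * 64)
        for j, lab in enumerate(i for i, m in zip(sm.labels, sm.bright_map)
                                if m >= 0):
            m = d.mu_A[:, j]
            lines.append(f"mu_A[{lab}]: {m.mean():.1f} "
                         f"(sd {m.std():.1f}) photons/frame")
        mb = d.mu_B.mean(axis=0)
        lines.append("mu_B per ROI: " +
                     ", ".join(f"{v:.0f}" for v in mb) + " photons/frame")
        pi = d.pi.mean(axis=0)
        lines.append("mean transition matrix (rows: " +
                     ", ".join(sm.labels) + "):")
        for row in pi:
            lines.append("    " + "  ".join(f"{v:.4f}" for v in row))
        lines.append("mean pi0: " +
                     "  ".join(f"{v:.3f}" for v in d.pi0.mean(axis=0)))
        lines.append("MH acceptance: " +
                     ", ".join(f"{k}={v:.2f}"
                               for k, v in d.accept_rates.items()))
        return "\n".join(lines)

    def plot_trace_overlay(self, roi: int, ax=None):
        """Measured trace with the sampled mean brightness superimposed."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        ov = self.trajectory_overlay(roi)
        ax.plot(ov["frame"], ov["w_adu"], lw=0.3, color="0.6",
                label="measured")
        ax.plot(ov["frame"], ov["mu_adu"], lw=1.2, color="C1",
                label="sampled mean")
        if "true_mu_adu" in ov:
            ax.plot(ov["frame"], ov["true_mu_adu"], lw=1.0, color="C2",
                    ls="--", label="ground truth")
        ax.set_xlabel("frame")
        ax.set_ylabel("brightness (ADU)")
        ax.legend(loc="upper right", fontsize=8)
        return ax

    def plot_count_histogram(self, ax=None, truth: Optional[np.ndarray] = None):
        """Pooled posterior histogram of B_r, optionally against truth."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        hist = self.count_summary.pooled_hist
        ax.bar(hist.index, hist.values, color="C0", alpha=0.7,
               label="posterior")
        if truth is None and self.model.traces.ground_truth is not None:
            truth = self.model.traces.ground_truth.counts
        if truth is not None:
            vals, cnts = np.unique(truth, return_counts=True)
            ax.step(vals, cnts / cnts.sum(), where="mid", color="C3",
                    label="ground truth")
        ax.set_xlabel("fluorophores per ROI")
        ax.set_ylabel("probability")
        ax.legend(fontsize=8)
        return ax
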
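"""Posterior summaries: count posteriors, error metrics, trace overlays."""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .gibbs import PosteriorDraws
from .states import TraceSet

__all__ = ["CountSummary", "count_posterior", "mean_error",
           "trajectory_overlay"]


@dataclass
class CountSummary:
    """Per-ROI fluorophore-count posterior summaries.

    ``table`` has one row per ROI (posterior mean, MAP, central 95%
    quantile interval of the integer count draws). Two pooled histograms
    are kept: ``pooled_hist`` pools every posterior draw of every ROI
    (the marginal count distribution including inference uncertainty) and
    ``estimate_hist`` histograms the per-ROI point estimates only.
    """

    samples: np.ndarray   # (n_draws, R)
    table: pd.DataFrame
    pooled_hist: pd.Series
    estimate_hist: pd.Series

    @property
    def mean(self) -> np.ndarray:
        return self.table["mean"].to_numpy()

    @property
    def map(self) -> np.ndarray:
        return self.table["map"].to_numpy()


def _mode(values: np.ndarray) -> int:
    v, c = np.unique(values, return_counts=True)
    return int(v[np.argmax(c)])


def count_posterior(draws: PosteriorDraws) -> CountSummary:
    """Summarise the per-sweep counts B_r of post-burn-in draws."""
    counts = np.asarray(draws.counts)
    if counts.size == 0:
        raise ValueError("empty posterior draws")
    R = counts.shape[1]
    rows = []
    for r in range(R):
        c = counts[:, r]
        lo, hi = np.quantile(c, [0.025, 0.975], method="closest_observation")
        rows.append({
            "roi": r,
            "mean": float(c.mean()),
            "map": _mode(c),
            "ci_low": int(lo),
            "ci_high": int(hi),
        })
    table = pd.DataFrame(rows).set_index("roi")
    pooled = pd.Series(counts.ravel()).value_counts(normalize=True).sort_index()
    est = pd.Series(np.round(table["mean"]).astype(int)) \
        .value_counts(normalize=True).sort_index()
    return CountSummary(counts, table, pooled, est)


def mean_error(summary: CountSummary, truth: np.ndarray) -> dict:
    """Signed and absolute counting errors against known ground truth.

    Uses the posterior mean as the per-ROI estimate. Returns the mean
    signed error, mean absolute error, max absolute error of the point
    estimates, the worst deviation of any retained draw, and a per-ROI
    table of signed errors.
    """
    truth = np.asarray(truth, dtype=float)
    est = summary.mean
    if truth.shape != est.shape:
        raise ValueError("truth must provide one count per ROI")
    signed = est - truth
    per_draw = np.abs(summary.samples - truth[None, :])
    table = pd.DataFrame({
        "estimate": est,
        "map": summary.map,
        "truth": truth,
        "error": signed,
    })
    return {
        "mean_error": float(signed.mean()),
        "mean_abs_error": float(np.abs(signed).mean()),
        "max_abs_error": float(np.abs(signed).max()),
        "max_draw_deviation": float(per_draw.max()),
        "table": table,
    }


def trajectory_overlay(
    draws: PosteriorDraws,
    traces: TraceSet,
    roi: int,
    which: str = "best",
) -> pd.DataFrame:
    """Per-frame sampled mean brightness for one ROI, for plotting.

    Reconstructs mu_n^r (photons/frame) from a chosen stored draw
    (default: the highest log-posterior draw) and, when the trace set
    carries simulation ground truth, the true mean brightness alongside.
    Columns are on both the photon scale and the ADU scale (x gain).
    """
    if not 0 <= roi < traces.R:
        raise IndexError("roi out of range")
    if which == "best":
        trajs = draws.best["trajs"][roi]
        loads = draws.best["loads"][roi]
        params = draws.best["params"]
    else:
        idx = int(which)
        pos = draws.traj_sweeps.index(draws.sweep_index[idx]) \
            if draws.sweep_index[idx] in draws.traj_sweeps else None
        if pos is None:
            raise ValueError("trajectories were not stored for that draw")
        trajs = draws.traj_draws[pos][roi]
        loads = draws.loads[idx, roi]
        params = draws.best["params"]
    bright = draws.state_model.state_brightness(params.mu_A)
    mu = params.mu_B[roi] + (loads[:, None] * bright[trajs]).sum(axis=0)
    out = pd.DataFrame({
        "frame": np.arange(traces.N),
        "w_adu": traces.w[roi],
        "mu_photons": mu,
        "mu_adu": mu * params.gain,
    })
    gt = traces.ground_truth
    if gt is not None and gt.trajectories is not None:
        tb = gt.state_model.state_brightness(gt.params.mu_A)
        true_mu = gt.params.mu_B[roi] + tb[gt.trajectories[roi]].sum(axis=0)
        out["true_mu_photons"] = true_mu
        out["true_mu_adu"] = true_mu * gt.params.gain
    return out
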
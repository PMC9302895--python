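"""Trace and results serialization.

Traces travel as plain CSV (frame index column plus one ADU column per
ROI) with gain and frame period in a JSON sidecar ``<stem>.meta.json``;
when the sidecar is absent the reader falls back to ``# key = value``
comment lines embedded at the top of the CSV. Posterior draws go to an
HDF5 archive with the run configuration, seed and package version
embedded — archives without provenance are rejected on read.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Union

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .gibbs import InferenceConfig, PosteriorDraws
from .states import GroundTruth, ModelParams, PhotoStateModel, TraceSet

__all__ = [
    "read_traces",
    "write_traces",
    "write_ground_truth",
    "read_ground_truth",
    "write_results",
    "read_results",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json") \
        if path.suffix != ".csv" else path.with_suffix(".meta.json")


def write_traces(traces: TraceSet, path: Union[str, Path]) -> None:
    """Write traces to CSV plus a JSON metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame(traces.w.T, columns=traces.roi_names)
    df.insert(0, "frame", np.arange(traces.N))
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {"gain": traces.gain, "frame_period": traces.frame_period}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_traces(
    path: Union[str, Path],
    gain: Optional[float] = None,
    frame_period: Optional[float] = None,
    roi_columns: Optional[list] = None,
) -> TraceSet:
    """Read a trace CSV; metadata from sidecar, header comments or kwargs."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    with open(path) as fh:
        comments = []
        for line in fh:
            if line.startswith("#"):
                comments.append(line)
            else:
                break
    for line in comments:
        body = line.lstrip("#").strip()
        if "=" in body:
            k, v = body.split("=", 1)
            meta.setdefault(k.strip(), float(v))
    if gain is not None:
        meta["gain"] = gain
    if frame_period is not None:
        meta["frame_period"] = frame_period
    if "gain" not in meta:
        raise ValueError(f"{path}: missing required metadata field 'gain'")
    if "frame_period" not in meta:
        raise ValueError(
            f"{path}: missing required metadata field 'frame_period'"
        )
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values in trace table")
    cols = roi_columns or [c for c in df.columns if c != "frame"]
    if not cols:
        raise ValueError(f"{path}: no ROI columns found")
    w = df[cols].to_numpy(dtype=float).T
    if np.any(w < 0):
        raise ValueError(f"{path}: negative ADU values")
    return TraceSet(w, float(meta["frame_period"]), float(meta["gain"]),
                    roi_names=list(cols))


def write_ground_truth(traces: TraceSet, path: Union[str, Path]) -> None:
    """Persist simulation ground truth (counts + parameters) as JSON."""
    gt = traces.ground_truth
    if gt is None:
        raise ValueError("trace set carries no ground truth")
    payload = {
        "counts": gt.counts.tolist(),
        "pi": gt.params.pi.tolist(),
        "pi0": gt.params.pi0.tolist(),
        "mu_A": gt.params.mu_A.tolist(),
        "mu_B": gt.params.mu_B.tolist(),
        "gain": gt.params.gain,
        "state_labels": list(gt.state_model.labels),
        "bright_map": list(gt.state_model.bright_map),
        "allowed": gt.state_model.allowed.astype(int).tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path: Union[str, Path]) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    model = PhotoStateModel(tuple(d["state_labels"]), tuple(d["bright_map"]),
                            np.array(d["allowed"], dtype=bool))
    params = ModelParams(np.array(d["pi0"]), np.array(d["pi"]),
                         np.array(d["mu_A"]), np.array(d["mu_B"]), d["gain"])
    return GroundTruth(np.array(d["counts"]), params, model)


def write_results(draws: PosteriorDraws, path: Union[str, Path],
                  seed: Optional[int] = None) -> None:
    """Posterior draws to an HDF5 archive with embedded provenance."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(dataclasses.asdict(draws.config))
        f.attrs["seed"] = draws.config.seed if seed is None else seed
        f.attrs["version"] = __version__
        f.create_dataset("counts", data=draws.counts, compression="gzip")
        f.create_dataset("loads", data=draws.loads, compression="gzip")
        f.create_dataset("log_posterior", data=draws.log_posterior)
        f.create_dataset("sweep_index", data=draws.sweep_index)
        p = f.create_group("params")
        p.create_dataset("mu_A", data=draws.mu_A)
        p.create_dataset("mu_B", data=draws.mu_B)
        p.create_dataset("pi", data=draws.pi)
        p.create_dataset("pi0", data=draws.pi0)
        t = f.create_group("trajectories")
        t.create_dataset("sweeps", data=np.asarray(draws.traj_sweeps, int))
        for s, arr in zip(draws.traj_sweeps, draws.traj_draws):
            t.create_dataset(f"sweep_{s}", data=arr, compression="gzip")
        b = f.create_group("best")
        b.attrs["log_posterior"] = draws.best["log_posterior"]
        b.attrs["sweep"] = draws.best.get("sweep", -1)
        if "trajs" in draws.best:
            b.create_dataset("trajs", data=draws.best["trajs"],
                             compression="gzip")
            b.create_dataset("loads", data=draws.best["loads"])
            bp = draws.best["params"]
            b.create_dataset("mu_A", data=bp.mu_A)
            b.create_dataset("mu_B", data=bp.mu_B)
            b.create_dataset("pi", data=bp.pi)
            b.create_dataset("pi0", data=bp.pi0)
            b.attrs["gain"] = bp.gain
        m = f.create_group("state_model")
        m.attrs["labels"] = json.dumps(list(draws.state_model.labels))
        m.attrs["bright_map"] = json.dumps(list(draws.state_model.bright_map))
        m.create_dataset("allowed",
                         data=draws.state_model.allowed.astype(np.uint8))


def read_results(path: Union[str, Path]) -> PosteriorDraws:
    """Load a draws archive; refuses archives without embedded config."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "config" not in f.attrs:
            raise ValueError(f"{path}: archive has no embedded run config")
        config = InferenceConfig(**json.loads(f.attrs["config"]))
        m = f["state_model"]
        model = PhotoStateModel(
            tuple(json.loads(m.attrs["labels"])),
            tuple(json.loads(m.attrs["bright_map"])),
            m["allowed"][()].astype(bool),
        )
        best = {"log_posterior": float(f["best"].attrs["log_posterior"]),
                "sweep": int(f["best"].attrs["sweep"])}
        if "trajs" in f["best"]:
            b = f["best"]
            best.update({
                "trajs": b["trajs"][()],
                "loads": b["loads"][()],
                "params": ModelParams(b["pi0"][()], b["pi"][()],
                                      b["mu_A"][()], b["mu_B"][()],
                                      float(b.attrs["gain"])),
            })
        sweeps = [int(s) for s in f["trajectories/sweeps"][()]]
        from .states import LatentConfiguration
        traj_draws = [f[f"trajectories/sweep_{s}"][()] for s in sweeps]
        loads = f["loads"][()]
        latent = LatentConfiguration(
            loads[-1],
            traj_draws[-1] if traj_draws else
            np.zeros_like(loads[-1])[..., None],
            config.gamma,
        ) if len(loads) else None
        return PosteriorDraws(
            counts=f["counts"][()], loads=loads,
            mu_A=f["params/mu_A"][()], mu_B=f["params/mu_B"][()],
            pi=f["params/pi"][()], pi0=f["params/pi0"][()],
            log_posterior=f["log_posterior"][()],
            sweep_index=f["sweep_index"][()],
            traj_sweeps=sweeps, traj_draws=traj_draws,
            best=best, accept_rates={}, config=config,
            state_model=model, final_latent=latent,
        )
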
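"""Synthetic multi-task clinical-style time series with planted
cross-task, cross-timestep dependencies.

The generator emulates the statistical structure the sharing mechanism
exploits: ``latent_dim`` independent AR(1) processes drive all observed
features through a fixed linear mixing plus Gaussian observation noise,
and each task's binary outcome depends on the shared latent state in a
task-specific time window, with the windows of successive tasks shifted
``cross_task_lag`` steps later.  Task i's outcome is therefore partly
predictable from the features most relevant to task i-1 at earlier
timesteps — a causal cross-task dependency — on top of a task-specific
latent component.  Intercepts are calibrated so realized positive rates
hit their targets; class imbalance mimics decreasing event frequency
with outcome severity.

Timesteps are 1-based in all file formats (recorded in the sidecar).
"""

from __future__ import annotations

import json
import os

import h5py
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .config import SyntheticSpec
from .data import Batch


class CalibrationError(RuntimeError):
    """Raised when no intercept attains the requested positive rate."""


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / (sd if sd > 0 else 1.0)


def _calibrate_intercept(signal: np.ndarray, target: float) -> float:
    """Solve mean(sigmoid(signal + b)) = target for b on a bounded range."""
    def gap(b):
        return expit(signal + b).mean() - target

    lo, hi = -60.0, 60.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise CalibrationError(
            f"positive rate {target} unattainable within intercept bounds")
    return brentq(gap, lo, hi, xtol=1e-10)


def task_windows(spec: SyntheticSpec) -> list[tuple[int, int]]:
    """Half-open 0-based [start, stop) label-relevance window per task."""
    return [(i * spec.cross_task_lag, i * spec.cross_task_lag + spec.window)
            for i in range(spec.M)]


def generate(spec: SyntheticSpec) -> tuple[Batch, dict]:
    """Draw one dataset; returns the Batch and the ground-truth latents.

    The latents dict carries everything an oracle needs: the AR(1)
    paths ``z`` (N, T, latent_dim), per-task logits, windows, mixing
    matrix and label-direction vectors.
    """
    rng = np.random.default_rng(spec.seed)
    N, T, K = spec.n_samples, spec.T, spec.latent_dim

    # unit-variance AR(1) latents
    z = np.empty((N, T, K))
    z[:, 0] = rng.standard_normal((N, K))
    innov_sd = np.sqrt(1.0 - spec.ar_coeff**2)
    for t in range(1, T):
        z[:, t] = spec.ar_coeff * z[:, t - 1] \
            + innov_sd * rng.standard_normal((N, K))

    mixing = rng.standard_normal((K, spec.d)) / np.sqrt(K)
    x = z @ mixing + spec.noise_sd * rng.standard_normal((N, T, spec.d))

    def unit(v):
        return v / np.linalg.norm(v)

    w_shared = unit(rng.standard_normal(K))
    w_tasks = [unit(rng.standard_normal(K)) for _ in range(spec.M)]

    windows = task_windows(spec)
    rho = spec.shared_fraction
    ys, logits = [], []
    for i, (lo, hi) in enumerate(windows):
        zbar = z[:, lo:hi].mean(axis=1)              # (N, K)
        shared_part = _standardize(zbar @ w_shared)
        if i == 0:
            signal = shared_part
        else:
            own = _standardize(zbar @ w_tasks[i])
            signal = rho * shared_part + np.sqrt(1.0 - rho**2) * own
        signal = spec.effect_size * _standardize(signal)
        b = _calibrate_intercept(signal, spec.positive_rates[i])
        p = expit(signal + b)
        ys.append(1 + (rng.uniform(size=N) < p).astype(int))
        logits.append(signal + b)

    batch = Batch(x, ys, [2] * spec.M)
    latents = {"z": z, "logits": logits, "windows": windows,
               "mixing": mixing, "w_shared": w_shared, "w_tasks": w_tasks}
    return batch, latents


# ---------------------------------------------------------------------------
# persistence: long-form CSV directory or a single HDF5 file
# ---------------------------------------------------------------------------

def write_dataset(batch: Batch, path: str,
                  spec: SyntheticSpec | None = None) -> None:
    """Write a Batch losslessly.

    A path ending in ``.h5``/``.hdf5`` produces one HDF5 file; anything
    else is treated as a directory holding ``features.csv`` (long form:
    sample_id, timestep, f1..fd), ``labels.csv`` (sample_id,
    task_1..task_M) and a JSON sidecar with the generating spec and the
    1-based indexing convention.
    """
    meta = {"timestep_indexing": "1-based",
            "task_classes": list(batch.task_classes),
            "spec": None if spec is None else spec.__dict__ | {
                "positive_rates": list(spec.positive_rates)}}
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "w") as f:
            f.create_dataset("x", data=batch.x)
            for i, yy in enumerate(batch.y):
                f.create_dataset(f"y_task_{i + 1}", data=yy)
            f.attrs["meta"] = json.dumps(meta)
        return
    os.makedirs(path, exist_ok=True)
    n, t, d = batch.x.shape
    feat = pd.DataFrame(batch.x.reshape(n * t, d),
                        columns=[f"f{k + 1}" for k in range(d)])
    feat.insert(0, "timestep", np.tile(np.arange(1, t + 1), n))
    feat.insert(0, "sample_id", np.repeat(np.arange(n), t))
    # default float formatting is shortest-round-trip, hence lossless
    feat.to_csv(os.path.join(path, "features.csv"), index=False)
    labels = pd.DataFrame({"sample_id": np.arange(n)} | {
        f"task_{i + 1}": yy for i, yy in enumerate(batch.y)})
    labels.to_csv(os.path.join(path, "labels.csv"), index=False)
    with open(os.path.join(path, "dataset.json"), "w") as fh:
        json.dump(meta, fh, indent=2)


def read_dataset(path: str) -> Batch:
    """Inverse of write_dataset; validates label ranges on load."""
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "r") as f:
            meta = json.loads(f.attrs["meta"])
            x = f["x"][:]
            ys = []
            i = 1
            while f"y_task_{i}" in f:
                ys.append(f[f"y_task_{i}"][:])
                i += 1
        return Batch(x, ys, meta["task_classes"])
    try:
        feat = pd.read_csv(os.path.join(path, "features.csv"),
                           float_precision="round_trip")
        labels = pd.read_csv(os.path.join(path, "labels.csv"))
        with open(os.path.join(path, "dataset.json")) as fh:
            meta = json.load(fh)
    except (OSError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed dataset at {path}: {exc}") from exc
    n = labels.shape[0]
    t = int(feat["timestep"].max())
    fcols = [c for c in feat.columns if c.startswith("f")]
    feat = feat.sort_values(["sample_id", "timestep"])
    x = feat[fcols].to_numpy().reshape(n, t, len(fcols))
    ys = [labels[c].to_numpy()
          for c in labels.columns if c.startswith("task_")]
    return Batch(x, ys, meta["task_classes"])
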
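"""Optimisation and evaluation: Adam training loop, AUROC, multi-seed
variant comparisons and hyper-parameter sweeps.

Evaluation follows the standard protocol for this family of models:
per-task AUROC, reported as mean +/- standard error over independently
seeded runs on a common train/test split, plus a macro average.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._autodiff import Tensor
from .config import ConfigError, ModelConfig, TrainSpec
from .data import Batch
from .network import GMTLNetwork

logger = logging.getLogger("gmtl")


class Adam:
    """Adaptive-moment optimiser over the network's parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 0.001,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainResult:
    """Loss trace (one entry per epoch) of a completed run."""

    epoch_losses: list[float] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": np.arange(1, len(self.epoch_losses) + 1),
                             "loss": self.epoch_losses})


def train(net: GMTLNetwork, batch: Batch, spec: TrainSpec,
          shuffle_seed: int | None = None) -> TrainResult:
    """Mini-batch gradient descent on the weighted multi-task loss.

    Deterministic given the network seed and ``shuffle_seed`` (defaults
    to the network's config seed).
    """
    if batch.num_tasks != net.config.num_tasks:
        raise ConfigError("batch task count does not match model config")
    rng = np.random.default_rng(
        net.config.seed if shuffle_seed is None else shuffle_seed)
    opt = Adam(net.trainable(), lr=spec.lr)
    result = TrainResult()
    n = batch.n_samples
    for epoch in range(spec.epochs):
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, spec.batch_size):
            idx = perm[start:start + spec.batch_size]
            sub = batch.subset(idx)
            net.zero_grad()
            loss = net.loss(sub.x, sub.y)
            val = loss.item()
            if not np.isfinite(val):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch + 1}, "
                    f"step {start // spec.batch_size + 1}")
            loss.backward()
            opt.step()
            losses.append(val)
        result.epoch_losses.append(float(np.mean(losses)))
        if spec.log_every and (epoch + 1) % spec.log_every == 0:
            logger.info("epoch %d/%d loss %.5f", epoch + 1, spec.epochs,
                        result.epoch_losses[-1])
    return result


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve as the Mann-Whitney rank statistic.

    Equals P(score+ > score-) + 0.5 P(tie) over all positive-negative
    pairs; ties receive average ranks, so the result matches an
    all-pairs count exactly.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: both classes must be present")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def evaluate(net: GMTLNetwork, batch: Batch) -> list[float]:
    """Per-task AUROC; for binary tasks the positive class is class 2."""
    probs = net.predict_proba(batch.x)
    out = []
    for p, yy, c in zip(probs, batch.y, batch.task_classes):
        if c != 2:
            raise ValueError("AUROC evaluation requires binary tasks")
        out.append(auroc(p[:, 1], yy == 2))
    return out


@dataclass
class EvalReport:
    """Per-(setting, task) AUROC mean and standard error over seeds."""

    table: pd.DataFrame
    n_train: int = 0
    n_test: int = 0

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False)

    def __str__(self) -> str:
        head = (f"train/test = {self.n_train}/{self.n_test}\n"
                if self.n_train else "")
        return head + self.table.to_string(index=False,
                                           float_format=lambda v: f"{v:.4f}")


def _aggregate(rows: list[dict], key: str) -> pd.DataFrame:
    """Mean +/- SE per (setting, task) plus the macro 'Average' column."""
    df = pd.DataFrame(rows)
    records = []
    for setting, grp in df.groupby(key, sort=False):
        runs = grp.pivot(index="seed", columns="task", values="auroc")
        runs["Average"] = runs.mean(axis=1)
        for task in runs.columns:
            vals = runs[task].to_numpy()
            se = (vals.std(ddof=1) / np.sqrt(len(vals))
                  if len(vals) > 1 else 0.0)
            records.append({key: setting, "task": task,
                            "auroc_mean": vals.mean(), "auroc_se": se})
    return pd.DataFrame(records)


def _run_setting(config: ModelConfig, train_batch: Batch, test_batch: Batch,
                 spec: TrainSpec) -> list[list[float]]:
    per_seed = []
    for seed in spec.seeds:
        cfg = dataclasses.replace(config, seed=seed)
        net = GMTLNetwork(cfg)
        train(net, train_batch, spec)
        per_seed.append(evaluate(net, test_batch))
    return per_seed


def compare_variants(batch: Batch, variants: list[str], config: ModelConfig,
                     spec: TrainSpec, n_train: int,
                     split_seed: int = 0) -> EvalReport:
    """Train each variant across seeds on one shared split; report AUROC.

    All variants see the identical train/test split so the comparison
    is paired across seeds.
    """
    if len(variants) < 1:
        raise ConfigError("need at least one variant")
    tr, te = batch.split(n_train, seed=split_seed)
    rows = []
    for k, variant in enumerate(variants):
        cfg = dataclasses.replace(config, variant=variant)
        try:
            per_seed = _run_setting(cfg, tr, te, spec)
        except Exception as exc:
            raise RuntimeError(f"variant {variant!r} failed: {exc}") from exc
        for seed, aucs in zip(spec.seeds, per_seed):
            for i, a in enumerate(aucs):
                # position-tagged so repeated variant names stay distinct
                rows.append({"variant": f"{k}#{variant}", "seed": seed,
                             "task": f"task_{i + 1}", "auroc": a})
    table = _aggregate(rows, "variant")
    table["variant"] = table["variant"].str.split("#", n=1).str[1]
    return EvalReport(table, n_train=tr.n_samples, n_test=te.n_samples)


def sweep(batch: Batch, grid: dict[str, list], config: ModelConfig,
          spec: TrainSpec, n_train: int, split_seed: int = 0) -> EvalReport:
    """Cross-product hyper-parameter evaluation (TopK fraction, depth).

    Grid keys are ModelConfig field names, e.g.
    ``{"topk_fraction": [0.1, ..., 0.4]}`` or ``{"num_layers": [1, 2, 3]}``.
    """
    if not grid:
        raise ConfigError("sweep grid must be nonempty")
    keys = list(grid)
    combos: list[dict] = [{}]
    for k in keys:
        combos = [c | {k: v} for c in combos for v in grid[k]]
    tr, te = batch.split(n_train, seed=split_seed)
    rows = []
    for combo in combos:
        cfg = dataclasses.replace(config, **combo)
        label = ",".join(f"{k}={combo[k]}" for k in keys)
        for seed, aucs in zip(spec.seeds, _run_setting(cfg, tr, te, spec)):
            for i, a in enumerate(aucs):
                rows.append({"setting": label, "seed": seed,
                             "task": f"task_{i + 1}", "auroc": a})
    return EvalReport(_aggregate(rows, "setting"),
                      n_train=tr.n_samples, n_test=te.n_samples)


def plot_sweep(report: EvalReport, path: str, key: str = "setting") -> None:
    """Line plot of per-task AUROC across sweep settings (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for task, grp in report.table.groupby("task"):
        ax.errorbar(grp[key], grp["auroc_mean"], yerr=grp["auroc_se"],
                    marker="o", label=task)
    ax.set_xlabel(key)
    ax.set_ylabel("AUROC")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
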
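"""Model/Results front end.

``GMTLModel`` binds a dataset to a configuration; ``fit`` runs the
optimisation and returns a ``GMTLResults`` carrying the trained
network, the loss trace and evaluation helpers, in the style of
statistical modelling packages:

    >>> model = GMTLModel(batch, variant="full", topk_fraction=0.2)
    >>> res = model.fit(epochs=50, seed=1)
    >>> print(res.summary())
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .config import ModelConfig, TrainSpec
from .data import Batch
from .network import GMTLNetwork
from .training import TrainResult, evaluate, train


class GMTLModel:
    """Cross-timestep feature-sharing multi-task forecaster bound to data.

    Parameters not passed explicitly are inferred from the batch
    (number of tasks, sequence length, feature dimension, classes).
    """

    def __init__(self, batch: Batch, config: ModelConfig | None = None,
                 **overrides):
        self.batch = batch
        if config is None:
            fields = dict(num_tasks=batch.num_tasks,
                          seq_len=batch.x.shape[1],
                          feat_dim=batch.x.shape[2],
                          task_classes=list(batch.task_classes))
            fields.update(overrides)
            config = ModelConfig(**fields)
        elif overrides:
            config = dataclasses.replace(config, **overrides)
        if config.num_tasks != batch.num_tasks:
            raise ValueError("config num_tasks does not match batch")
        self.config = config

    @classmethod
    def from_arrays(cls, x: np.ndarray, ys: list[np.ndarray],
                    **overrides) -> "GMTLModel":
        return cls(Batch(x, ys), **overrides)

    def fit(self, spec: TrainSpec | None = None, seed: int | None = None,
            **spec_overrides) -> "GMTLResults":
        """Train with Adam; returns the fitted results object.

        ``seed`` overrides the config seed (weight init + batch order).
        Keyword overrides (epochs=..., lr=...) patch the TrainSpec.
        """
        if spec is None:
            spec = TrainSpec(**spec_overrides)
        elif spec_overrides:
            spec = dataclasses.replace(spec, **spec_overrides)
        cfg = self.config if seed is None \
            else dataclasses.replace(self.config, seed=seed)
        net = GMTLNetwork(cfg)
        trace = train(net, self.batch, spec)
        return GMTLResults(self, net, trace, spec)


class GMTLResults:
    """Fitted model: trained parameters, loss trace, evaluation."""

    def __init__(self, model: GMTLModel, network: GMTLNetwork,
                 trace: TrainResult, spec: TrainSpec):
        self.model = model
        self.network = network
        self.trace = trace
        self.train_spec = spec

    @property
    def loss_trace(self) -> list[float]:
        return self.trace.epoch_losses

    def predict_proba(self, x: np.ndarray) -> list[np.ndarray]:
        return self.network.predict_proba(x)

    def predict(self, x: np.ndarray) -> list[np.ndarray]:
        """Per-task 1-based class predictions."""
        return [1 + p.argmax(axis=-1) for p in self.predict_proba(x)]

    def auroc(self, batch: Batch | None = None) -> list[float]:
        """Per-task AUROC on the given batch (training data by default)."""
        return evaluate(self.network, batch or self.model.batch)

    def save(self, path: str) -> None:
        self.network.save(path)

    def summary(self) -> str:
        cfg = self.network.config
        n_params = sum(p.data.size for p in self.network.params.values())
        aucs = self.auroc()
        lines = [
            "G-MTL: cross-timestep feature-sharing multi-task forecaster",
            "=" * 60,
            f"variant:          {cfg.variant}",
            f"tasks / T / d:    {cfg.num_tasks} / {cfg.seq_len} / "
            f"{cfg.feat_dim}",
            f"encoder:          {cfg.encoder_layers}-layer LSTM, "
            f"hidden {cfg.encoder_hidden}",
            f"sharing layers:   {cfg.num_layers}  (TopK fraction "
            f"{cfg.topk_fraction:.2f})",
            f"parameters:       {n_params}",
            f"epochs trained:   {len(self.loss_trace)}"
            f"  (lr {self.train_spec.lr}, batch "
            f"{self.train_spec.batch_size})",
            f"final loss:       {self.loss_trace[-1]:.5f}"
            if self.loss_trace else "final loss:       n/a",
            "-" * 60,
        ]
        for i, a in enumerate(aucs):
            lines.append(f"task_{i + 1} train AUROC:  {a:.4f}")
        lines.append(f"average train AUROC: {np.mean(aucs):.4f}")
        lines.append("=" * 60)
        return "\n".join(lines)
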
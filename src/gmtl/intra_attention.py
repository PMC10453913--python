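"""Intra-task global dynamic dependencies via self-attention.

Each task's T x d feature sequence attends over itself: linear Q/K/V
projections, an unmasked row-wise softmax over the T x T score matrix
(by default without the 1/sqrt(d) temperature of conventional scaled
dot-product attention — the model is defined with raw scores; set
``scaled=True`` for the conventional form), and a residual fusion of
the attended features with the input:

    C = F_in + softmax(Q K^T) V

These functions operate on a single sequence and are the definitional
implementation; the batched network mirrors them exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

STAGES = ("input", "attended", "fused", "shared", "aggregated", "output")


@dataclass
class FeatureSequence:
    """A T x d per-timestep feature matrix for one task at one stage."""

    values: np.ndarray
    task_id: int = 1
    layer: int = 0
    stage: str = "input"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("FeatureSequence values must be a T x d matrix")
        if not np.isfinite(self.values).all():
            raise ValueError("FeatureSequence values must be finite")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")


@dataclass
class AttentionProjections:
    """Task- and layer-specific Q/K/V linear maps (d -> d, with bias)."""

    wq: np.ndarray
    wk: np.ndarray
    wv: np.ndarray
    bq: np.ndarray | None = None
    bk: np.ndarray | None = None
    bv: np.ndarray | None = None

    def __post_init__(self):
        for name in ("wq", "wk", "wv"):
            w = np.asarray(getattr(self, name), dtype=float)
            if w.ndim != 2 or w.shape[0] != w.shape[1]:
                raise ValueError(f"{name} must be a square d x d matrix")
            setattr(self, name, w)
        d = self.wq.shape[0]
        for name in ("bq", "bk", "bv"):
            b = getattr(self, name)
            b = np.zeros(d) if b is None else np.asarray(b, dtype=float)
            if b.shape != (d,):
                raise ValueError(f"{name} must have length d={d}")
            setattr(self, name, b)

    @classmethod
    def identity(cls, d: int) -> "AttentionProjections":
        eye = np.eye(d)
        return cls(eye.copy(), eye.copy(), eye.copy())


def project_qkv(x: FeatureSequence, proj: AttentionProjections):
    """Apply the Q/K/V linear maps row-wise to a T x d input sequence."""
    vals = x.values
    d = proj.wq.shape[0]
    if vals.shape[1] != d:
        raise ValueError(
            f"feature dim {vals.shape[1]} does not match projections (d={d})")
    q = vals @ proj.wq + proj.bq
    k = vals @ proj.wk + proj.bk
    v = vals @ proj.wv + proj.bv
    return q, k, v


def attention_weights(q: np.ndarray, k: np.ndarray,
                      scaled: bool = False) -> np.ndarray:
    """Row-wise softmax of Q K^T; each query row attends over all T keys."""
    scores = q @ k.T
    if scaled:
        scores = scores / np.sqrt(q.shape[1])
    scores = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(scores)
    return e / e.sum(axis=1, keepdims=True)


def self_attend(q: np.ndarray, k: np.ndarray, v: np.ndarray, *,
                scaled: bool = False, task_id: int = 1,
                layer: int = 1) -> FeatureSequence:
    """Unmasked self-attention: softmax(Q K^T) V over all T timesteps."""
    for name, m in (("Q", q), ("K", k), ("V", v)):
        bad = ~np.isfinite(m).all(axis=1)
        if bad.any():
            raise ValueError(
                f"{name} has non-finite entries at row {int(np.where(bad)[0][0])}")
    if not (q.shape == k.shape == v.shape):
        raise ValueError("Q, K, V must share shape T x d")
    w = attention_weights(q, k, scaled=scaled)
    return FeatureSequence(w @ v, task_id=task_id, layer=layer,
                           stage="attended")


def residual_fuse(x: FeatureSequence,
                  attended: FeatureSequence) -> FeatureSequence:
    """Elementwise residual fusion C = F_in + F_attended."""
    if x.values.shape != attended.values.shape:
        raise ValueError(
            f"shape mismatch: {x.values.shape} vs {attended.values.shape}")
    return FeatureSequence(x.values + attended.values, task_id=x.task_id,
                           layer=attended.layer, stage="fused")
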
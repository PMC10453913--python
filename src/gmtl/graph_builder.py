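"""Adaptive causal TopK graph over (task, timestep) nodes.

For a target task i, the adjacency links source nodes (task j != i,
timestep s) to target nodes (i, t).  Edge strength is the cosine
similarity of shared-space features; only edges with s <= t (earlier or
co-temporal information) are candidates, and per (target node, source
task) the TopK most similar candidates are kept, with

    K = max(1, ceil(topk_fraction * t))   (t counted 1-based)

so that every target node keeps at least one inbound edge per source
task.  Ties in similarity are broken in favour of the earlier source
timestep.  Fixed adjacencies used by ablations (causal-complete and
same-timestep-only) are also provided.

Arrays are 0-indexed; entry ``[s, t]`` refers to source timestep s+1
and target timestep t+1 in the 1-based convention used throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import ConfigError
from .intra_attention import FeatureSequence


@dataclass
class SharedSpaceMap:
    """Linear map G (d -> d) into the task-shared latent space."""

    weight: np.ndarray
    bias: np.ndarray | None = None

    def __post_init__(self):
        self.weight = np.asarray(self.weight, dtype=float)
        if self.weight.ndim != 2 or self.weight.shape[0] != self.weight.shape[1]:
            raise ValueError("shared-space weight must be square d x d")
        d = self.weight.shape[0]
        self.bias = (np.zeros(d) if self.bias is None
                     else np.asarray(self.bias, dtype=float))
        if self.bias.shape != (d,):
            raise ValueError(f"shared-space bias must have length {d}")


@dataclass
class CrossTaskAdjacency:
    """Directed cross-task edges into one target task.

    ``similarity[j][s, t]`` is the cosine similarity mu between source
    node (task j, timestep s+1) and target node (timestep t+1);
    ``mask[j]`` is the binary edge indicator A on the same index grid.
    """

    target_task: int
    similarity: dict[int, np.ndarray] = field(default_factory=dict)
    mask: dict[int, np.ndarray] = field(default_factory=dict)
    topk_fraction: float = 1.0

    def validate(self) -> None:
        for j, a in self.mask.items():
            if np.any(np.tril(a, -1) != 0):
                raise ValueError(
                    f"causality violated: source task {j} has an edge s > t")

    def edge_list(self) -> list[tuple[int, int, int, int, float]]:
        """Edges as (source_task, s, target_task, t, mu), 1-based timesteps."""
        edges = []
        for j in sorted(self.mask):
            ss, tt = np.nonzero(self.mask[j])
            mu = self.similarity.get(j)
            for s, t in zip(ss, tt):
                val = float(mu[s, t]) if mu is not None else math.nan
                edges.append((j, int(s) + 1, self.target_task, int(t) + 1, val))
        return edges


def to_shared_space(c: FeatureSequence, g: SharedSpaceMap) -> FeatureSequence:
    """Map fused features row-wise into the shared space: C~ = G(C)."""
    if c.values.shape[1] != g.weight.shape[0]:
        raise ValueError(
            f"feature dim {c.values.shape[1]} does not match G "
            f"(d={g.weight.shape[0]})")
    return FeatureSequence(c.values @ g.weight + g.bias, task_id=c.task_id,
                           layer=c.layer, stage="shared")


def _unit_rows(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=-1, keepdims=True)
    zero = norms == 0
    if zero.any():
        warnings.warn("zero-norm shared-space row(s); their cosine "
                      "similarities are defined as 0", RuntimeWarning,
                      stacklevel=3)
    return np.where(zero, 0.0, x / np.where(zero, 1.0, norms))


def pairwise_cosine(source: FeatureSequence,
                    target: FeatureSequence) -> np.ndarray:
    """Cosine similarity mu[s, t] between all source/target timestep pairs.

    Zero-norm rows yield similarity 0 (with a warning) rather than NaN.
    """
    if source.task_id == target.task_id:
        raise ValueError("cross-task similarity requires distinct tasks")
    return _unit_rows(source.values) @ _unit_rows(target.values).T


def topk_count(fraction: float, t: int) -> int:
    """Edges kept for 1-based target timestep t: min(max(1, ceil(f*t)), t)."""
    return min(max(1, math.ceil(fraction * t)), t)


def causal_topk_mask(mu: np.ndarray, fraction: float) -> np.ndarray:
    """Binary causal TopK mask for one source task's T x T similarities."""
    T = mu.shape[0]
    mask = np.zeros((T, T), dtype=np.uint8)
    for t in range(T):  # 0-based; 1-based timestep is t + 1
        k = topk_count(fraction, t + 1)
        cand = mu[: t + 1, t]
        # stable sort on -mu keeps the earlier timestep first among ties
        order = np.argsort(-cand, kind="stable")[:k]
        mask[order, t] = 1
    return mask


def build_causal_topk(similarities: dict[int, np.ndarray],
                      topk_fraction: float,
                      target_task: int = 1) -> CrossTaskAdjacency:
    """Select, per target node and source task, the TopK causal edges."""
    if not (0.0 < topk_fraction <= 1.0):
        raise ConfigError(
            f"topk_fraction must be in (0, 1], got {topk_fraction}")
    adj = CrossTaskAdjacency(target_task=target_task,
                             topk_fraction=topk_fraction)
    for j, mu in similarities.items():
        mu = np.asarray(mu, dtype=float)
        if mu.ndim != 2 or mu.shape[0] != mu.shape[1]:
            raise ValueError("similarity matrices must be square T x T")
        adj.similarity[j] = mu
        adj.mask[j] = causal_topk_mask(mu, topk_fraction)
    return adj


def _fixed_adjacency(T: int, tasks: int, target: int,
                     mask: np.ndarray) -> CrossTaskAdjacency:
    adj = CrossTaskAdjacency(target_task=target, topk_fraction=1.0)
    for j in range(1, tasks + 1):
        if j != target:
            adj.mask[j] = mask.copy()
    return adj


def complete_graph(T: int, tasks: int, target: int,
                   causal: bool = True) -> CrossTaskAdjacency:
    """Static complete graph connecting all (earlier) nodes to each node.

    With ``causal=True`` (default) all s <= t edges are present, i.e.
    "all nodes to the current node"; ``causal=False`` lifts the
    constraint entirely for comparison.
    """
    base = np.triu(np.ones((T, T), dtype=np.uint8)) if causal \
        else np.ones((T, T), dtype=np.uint8)
    return _fixed_adjacency(T, tasks, target, base)


def same_timestep_graph(T: int, tasks: int, target: int) -> CrossTaskAdjacency:
    """Feature sharing restricted to co-temporal nodes only (s = t)."""
    return _fixed_adjacency(T, tasks, target, np.eye(T, dtype=np.uint8))
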
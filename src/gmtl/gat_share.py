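"""Cross-timestep feature sharing by graph attention.

Each target node (task i, timestep t) aggregates its own shared-space
feature and the features of its adjacency neighbours (task j, timestep
s <= t) after a common linear lift W (d -> d'):

    beta  = LeakyReLU( a^T [W h_target || W h_source] )
    alpha = softmax over {self} u {neighbours with A = 1}
    Z_t   = alpha_self W h_target + sum_neighbours alpha W h_source
    f_t   = sigma(Z_t)

W and the attention vector ``a`` are shared across all nodes within a
layer; a single attention head is used.  By the standard convention the
self node participates in the same softmax as the neighbours
(``self_in_softmax=True``); the literal alternative — neighbours-only
softmax with a unit self weight — is kept as an option.

These functions operate node-by-node on single sequences; the batched
network computes the identical quantities vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_builder import CrossTaskAdjacency
from .intra_attention import FeatureSequence

_ACTIVATIONS = {
    "elu": lambda z: np.where(z > 0, z, np.expm1(np.minimum(z, 0.0))),
    "relu": lambda z: np.maximum(z, 0.0),
    "tanh": np.tanh,
    "identity": lambda z: z,
}


@dataclass
class GatParams:
    """Shared GAT parameters for one layer: W (d -> d'), a (2d'), slopes."""

    weight: np.ndarray           # (d, d'), applied as h @ weight
    attn_vector: np.ndarray      # (2 d',)
    leaky_slope: float = 0.01
    out_activation: str = "elu"

    def __post_init__(self):
        self.weight = np.asarray(self.weight, dtype=float)
        self.attn_vector = np.asarray(self.attn_vector, dtype=float)
        if self.weight.ndim != 2:
            raise ValueError("GAT weight must be a d x d' matrix")
        if self.attn_vector.shape != (2 * self.weight.shape[1],):
            raise ValueError(
                f"attention vector must have length 2*d'="
                f"{2 * self.weight.shape[1]}")
        if self.leaky_slope <= 0:
            raise ValueError("leaky_slope must be > 0")
        if self.out_activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.out_activation!r}")

    @property
    def out_dim(self) -> int:
        return self.weight.shape[1]

    def activate(self, z: np.ndarray) -> np.ndarray:
        return _ACTIVATIONS[self.out_activation](z)


def _leaky(z: float, slope: float) -> float:
    return z if z > 0 else slope * z


def attention_logit(target_feat: np.ndarray, source_feat: np.ndarray,
                    params: GatParams) -> float:
    """Raw attention score beta = LeakyReLU(a^T [W target || W source])."""
    target_feat = np.asarray(target_feat, dtype=float)
    source_feat = np.asarray(source_feat, dtype=float)
    d = params.weight.shape[0]
    if target_feat.shape != (d,) or source_feat.shape != (d,):
        raise ValueError(f"node features must be vectors of length d={d}")
    wt = target_feat @ params.weight
    ws = source_feat @ params.weight
    pre = float(params.attn_vector @ np.concatenate([wt, ws]))
    return _leaky(pre, params.leaky_slope)


def normalize_attention(logits: dict, self_logit: float,
                        include_self: bool = True) -> dict:
    """Softmax-normalise attention scores over {self} u neighbours.

    Returns a dict with the neighbours' keys plus ``"self"``; the
    returned coefficients sum to 1.  With ``include_self=False`` the
    softmax runs over the neighbours only and the self weight is fixed
    at 1 (the literal reading of the normalisation set).
    """
    if include_self:
        keys = ["self"] + list(logits)
        vals = np.array([self_logit] + [logits[k] for k in logits])
    else:
        if not logits:
            return {"self": 1.0}
        keys = list(logits)
        vals = np.array([logits[k] for k in logits])
    e = np.exp(vals - vals.max())
    alpha = e / e.sum()
    out = dict(zip(keys, alpha))
    if not include_self:
        out["self"] = 1.0
    return out


def aggregate_node(target: np.ndarray, neighbors: list, alpha_self: float,
                   params: GatParams) -> np.ndarray:
    """Convex aggregation Z = alpha_self W target + sum alpha W source.

    ``neighbors`` is a list of (feature d-vector, alpha) pairs; the
    coefficients with ``alpha_self`` must sum to 1.
    """
    total = alpha_self + sum(a for _, a in neighbors)
    if abs(total - 1.0) > 1e-6:
        raise ValueError(
            f"attention coefficients must sum to 1, got {total:.8f}")
    z = alpha_self * (np.asarray(target, dtype=float) @ params.weight)
    for feat, a in neighbors:
        z = z + a * (np.asarray(feat, dtype=float) @ params.weight)
    return z


def gat_layer(all_tasks_shared_feats: list[FeatureSequence],
              adjacencies: list[CrossTaskAdjacency], params: GatParams,
              self_in_softmax: bool = True) -> list[FeatureSequence]:
    """One full graph-attention layer over all tasks.

    ``adjacencies[i]`` gives the inbound edges of task
    ``all_tasks_shared_feats[i].task_id``; outputs are T x d' sequences
    f = sigma(Z), one per task.
    """
    by_task = {fs.task_id: fs for fs in all_tasks_shared_feats}
    T = all_tasks_shared_feats[0].values.shape[0]
    outputs = []
    for fs, adj in zip(all_tasks_shared_feats, adjacencies):
        if adj.target_task != fs.task_id:
            raise ValueError("adjacency/target task mismatch")
        rows = np.empty((T, params.out_dim))
        for t in range(T):
            target_feat = fs.values[t]
            logits: dict = {}
            feats: dict = {}
            for j, mask in adj.mask.items():
                if mask.shape[1] != T:
                    raise IndexError("adjacency timestep range mismatch")
                for s in np.nonzero(mask[:, t])[0]:
                    if s >= T:
                        raise IndexError("adjacency references timestep "
                                         f"{s + 1} > T={T}")
                    feat = by_task[j].values[s]
                    logits[(j, int(s))] = attention_logit(target_feat, feat,
                                                          params)
                    feats[(j, int(s))] = feat
            self_logit = attention_logit(target_feat, target_feat, params)
            alpha = normalize_attention(logits, self_logit,
                                        include_self=self_in_softmax)
            if self_in_softmax:
                rows[t] = aggregate_node(
                    target_feat,
                    [(feats[k], alpha[k]) for k in logits],
                    alpha["self"], params)
            else:
                z = target_feat @ params.weight
                for k in logits:
                    z = z + alpha[k] * (feats[k] @ params.weight)
                rows[t] = z
        outputs.append(FeatureSequence(params.activate(rows),
                                       task_id=fs.task_id, layer=fs.layer,
                                       stage="output"))
    return outputs
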
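"""The full multi-task network: encoders, stacked sharing layers, heads.

Data flow per task i (batch of N samples, T timesteps, d features):

  1. a task-specific LSTM encoder (depth ``encoder_layers``) produces
     per-timestep hidden states F^0 (N x T x h);
  2. L sharing layers, each: intra-task self-attention with residual
     fusion (C = F + softmax(Q K^T) V), a shared-space map C~ = G(C),
     an adjacency over (task, timestep) nodes built per sample from
     cosine similarities of C~ (causal TopK for the full variant, or a
     fixed ablation graph), and graph attention aggregating neighbour
     features into f = sigma(Z);
  3. the T outputs are concatenated and a per-task linear head maps
     them to class scores.

Variant semantics:

  ``full``              learned causal TopK graph (the model proper)
  ``complete_graph``    fixed causal complete graph (all s <= t)
  ``no_intra_attention``uniform 1/T weights instead of Eq-style attention
  ``same_timestep``     edges only at s = t
  ``non_shared``        empty cross-task graph; GAT reduces to the self
                        node, so tasks train jointly but share nothing

The adjacency is recomputed per sample per layer inside the forward
pass — it depends on the instance's features and is not a learned
global parameter.  The TopK selection itself is a hard, non-smooth
choice; gradients flow through the attention weights on the selected
edges and through the shared-space features, not through the selection.
"""

from __future__ import annotations

import io
import json
import zipfile

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .config import ConfigError, ModelConfig
from .graph_builder import topk_count


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


def lstm_layer(x: Tensor, wx: Tensor, wh: Tensor, b: Tensor,
               hidden: int) -> Tensor:
    """One LSTM layer over (N, T, d_in) -> (N, T, hidden).

    Fused into a single graph node with a hand-written
    backpropagation-through-time, so the step loop runs on plain numpy.
    Gate layout along the 4h axis is [input, forget, output | cell].
    """
    h = hidden
    B, T, _ = x.shape
    dt = x.data.dtype
    xp = np.matmul(x.data, wx.data) + b.data          # (B, T, 4h)
    act = np.empty((B, T, 4 * h), dtype=dt)           # activated gates
    cells = np.empty((B, T, h), dtype=dt)
    tanh_c = np.empty((B, T, h), dtype=dt)
    hs = np.empty((B, T, h), dtype=dt)
    hprev = np.zeros((B, h), dtype=dt)
    cprev = np.zeros((B, h), dtype=dt)
    for t in range(T):
        pre = xp[:, t] + hprev @ wh.data
        a_t = act[:, t]
        np.negative(pre[:, :3 * h], out=a_t[:, :3 * h])
        np.exp(a_t[:, :3 * h], out=a_t[:, :3 * h])
        a_t[:, :3 * h] += 1.0
        np.reciprocal(a_t[:, :3 * h], out=a_t[:, :3 * h])  # sigmoid i,f,o
        np.tanh(pre[:, 3 * h:], out=a_t[:, 3 * h:])        # cell candidate
        i_g, f_g, o_g = (a_t[:, :h], a_t[:, h:2 * h], a_t[:, 2 * h:3 * h])
        g_g = a_t[:, 3 * h:]
        c_t = cells[:, t]
        np.multiply(f_g, cprev, out=c_t)
        c_t += i_g * g_g
        np.tanh(c_t, out=tanh_c[:, t])
        np.multiply(o_g, tanh_c[:, t], out=hs[:, t])
        hprev = hs[:, t]
        cprev = c_t
    out = Tensor(hs, _prev=(x, wx, wh, b))

    def bw(gout):
        dxp = np.empty((B, T, 4 * h), dtype=dt)
        dwh = np.zeros_like(wh.data)
        dh = np.zeros((B, h), dtype=dt)
        dc = np.zeros((B, h), dtype=dt)
        wh_t = wh.data.T
        for t in range(T - 1, -1, -1):
            a_t = act[:, t]
            i_g, f_g, o_g = (a_t[:, :h], a_t[:, h:2 * h], a_t[:, 2 * h:3 * h])
            g_g = a_t[:, 3 * h:]
            tc = tanh_c[:, t]
            dht = gout[:, t] + dh
            dc = dc + dht * o_g * (1.0 - tc * tc)
            da = dxp[:, t]
            cprev_t = cells[:, t - 1] if t > 0 else 0.0
            da[:, :h] = dc * g_g * i_g * (1.0 - i_g)            # input gate
            da[:, h:2 * h] = dc * cprev_t * f_g * (1.0 - f_g)   # forget gate
            da[:, 2 * h:3 * h] = dht * tc * o_g * (1.0 - o_g)   # output gate
            da[:, 3 * h:] = dc * i_g * (1.0 - g_g * g_g)        # candidate
            if t > 0:
                dwh += hs[:, t - 1].T @ da
            dh = da @ wh_t
            dc = dc * f_g
        if wh.requires_grad:
            wh._accum(dwh, own=True)
        if b.requires_grad:
            b._accum(dxp.sum(axis=(0, 1)), own=True)
        if wx.requires_grad:
            wx._accum(np.tensordot(x.data, dxp, axes=([0, 1], [0, 1])),
                      own=True)
        if x.requires_grad:
            x._accum(np.matmul(dxp, wx.data.T), own=True)

    out._backward = bw
    return out


class GMTLNetwork:
    """Parameter container + differentiable forward pass."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.params: dict[str, Tensor] = {}
        #: per layer, per target task: binary adjacency masks of the
        #: most recent forward pass (for inspection/export)
        self.last_adjacency: list[list[dict]] = []
        #: per layer, per target task: attention coefficients of the
        #: most recent forward pass, as (alpha array, source task order)
        self.last_attention: list[list[tuple]] = []
        self._init_params()

    # ------------------------------------------------------------------
    # parameters
    # ------------------------------------------------------------------

    def _add(self, name: str, value: np.ndarray) -> None:
        self.params[name] = Tensor(value.astype(self.config.dtype),
                                   requires_grad=True)

    def _init_params(self) -> None:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        h, dp = cfg.encoder_hidden, cfg.gat_dim
        for i in range(cfg.num_tasks):
            d_in = cfg.feat_dim
            for k in range(cfg.encoder_layers):
                self._add(f"enc{i}_l{k}_wx", _glorot(rng, d_in, 4 * h))
                self._add(f"enc{i}_l{k}_wh", _glorot(rng, h, 4 * h))
                b = np.zeros(4 * h)
                b[h:2 * h] = 1.0  # forget-gate bias
                self._add(f"enc{i}_l{k}_b", b)
                d_in = h
        for layer in range(cfg.num_layers):
            d_l = h if layer == 0 else dp
            for i in range(cfg.num_tasks):
                for nm in ("q", "k", "v"):
                    self._add(f"att{layer}_t{i}_w{nm}", _glorot(rng, d_l, d_l))
                    self._add(f"att{layer}_t{i}_b{nm}", np.zeros(d_l))
            self._add(f"g{layer}_w", _glorot(rng, d_l, d_l))
            self._add(f"g{layer}_b", np.zeros(d_l))
            self._add(f"gat{layer}_w", _glorot(rng, d_l, dp))
            self._add(f"gat{layer}_a", _glorot(rng, 2 * dp, 1, (2 * dp,)))
        for i, c in enumerate(cfg.task_classes):
            self._add(f"head{i}_w", _glorot(rng, cfg.seq_len * dp, c))
            self._add(f"head{i}_b", np.zeros(c))

    def trainable(self) -> list[Tensor]:
        return list(self.params.values())

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    # ------------------------------------------------------------------
    # forward
    # ------------------------------------------------------------------

    def _encode(self, x: Tensor, task: int) -> Tensor:
        """Task-specific LSTM over (N, T, d) -> (N, T, h)."""
        cfg = self.config
        seq = x
        for k in range(cfg.encoder_layers):
            seq = lstm_layer(seq,
                             self.params[f"enc{task}_l{k}_wx"],
                             self.params[f"enc{task}_l{k}_wh"],
                             self.params[f"enc{task}_l{k}_b"],
                             cfg.encoder_hidden)
        return seq

    def _self_attention(self, feats: Tensor, layer: int, task: int) -> Tensor:
        """Residual-fused intra-task attention on (N, T, d_l)."""
        cfg = self.config
        p = self.params
        v = ad.matmul(feats, p[f"att{layer}_t{task}_wv"]) \
            + p[f"att{layer}_t{task}_bv"]
        if cfg.variant == "no_intra_attention":
            # uniform 1/T weights on every timestep feature
            attended = v.mean(axis=1, keepdims=True) + Tensor(
                np.zeros((1, cfg.seq_len, 1), dtype=cfg.dtype))
            return feats + attended
        q = ad.matmul(feats, p[f"att{layer}_t{task}_wq"]) \
            + p[f"att{layer}_t{task}_bq"]
        k = ad.matmul(feats, p[f"att{layer}_t{task}_wk"]) \
            + p[f"att{layer}_t{task}_bk"]
        scores = ad.matmul(q, k.swapaxes(-1, -2))
        if cfg.scaled_attention:
            scores = scores * (1.0 / np.sqrt(q.shape[-1]))
        weights = ad.softmax(scores, axis=-1)
        return feats + ad.matmul(weights, v)

    def _layer_masks(self, shared: list[Tensor]) -> list[dict]:
        """Per-target-task dict of binary masks (N or 1, T_s, T_t).

        Built once per layer from detached shared-space values; the hard
        TopK selection carries no gradient.  For the learned variants the
        cosine similarities of each unordered task pair are computed once
        and transposed for the reverse direction.
        """
        cfg = self.config
        T, M = cfg.seq_len, cfg.num_tasks
        variant = cfg.variant
        if variant == "non_shared" or M == 1:
            return [{} for _ in range(M)]
        if variant == "complete_graph":
            base = (np.triu(np.ones((T, T), dtype=np.uint8))
                    if cfg.causal_complete
                    else np.ones((T, T), dtype=np.uint8))
            return [{j: base[None] for j in range(M) if j != i}
                    for i in range(M)]
        if variant == "same_timestep":
            eye = np.eye(T, dtype=np.uint8)[None]
            return [{j: eye for j in range(M) if j != i} for i in range(M)]
        # full / no_intra_attention: learned causal TopK from cosine sim
        vals = [s.data for s in shared]
        norms = [np.linalg.norm(v, axis=-1, keepdims=True) for v in vals]
        units = [np.where(n == 0, 0.0, v / np.where(n == 0, 1.0, n))
                 for v, n in zip(vals, norms)]
        N = vals[0].shape[0]
        rows = np.arange(N)[:, None]

        def topk(mu):
            mask = np.zeros(mu.shape, dtype=np.uint8)
            for t in range(T):
                k = topk_count(cfg.topk_fraction, t + 1)
                order = np.argsort(-mu[:, :t + 1, t], axis=1,
                                   kind="stable")[:, :k]
                mask[rows, order, t] = 1
            return mask

        masks: list[dict] = [{} for _ in range(M)]
        for a in range(M):
            for bb in range(a + 1, M):
                mu_ab = np.matmul(units[a], np.swapaxes(units[bb], -1, -2))
                masks[bb][a] = topk(mu_ab)              # source a -> target b
                masks[a][bb] = topk(np.swapaxes(mu_ab, -1, -2))
        return masks

    def _gat(self, shared: list[Tensor], layer: int) -> list[Tensor]:
        """Graph attention over all tasks' shared features (N, T, d_l)."""
        cfg = self.config
        w = self.params[f"gat{layer}_w"]
        a = self.params[f"gat{layer}_a"]
        dp = cfg.gat_dim
        a_tgt, a_src = a[:dp], a[dp:]
        lifted = [ad.matmul(s, w) for s in shared]        # (N, T, d')
        e_tgt = [ad.matmul(hh, a_tgt.reshape(dp, 1)) for hh in lifted]
        e_src = [ad.matmul(hh, a_src.reshape(dp, 1)) for hh in lifted]
        all_masks = self._layer_masks(shared)
        self.last_adjacency.append(all_masks)
        layer_alpha: list[tuple] = []
        self.last_attention.append(layer_alpha)
        outputs = []
        for i in range(cfg.num_tasks):
            masks = all_masks[i]
            N, T = shared[i].shape[0], cfg.seq_len
            # logits: self (N,T,1) then each source task (N,T_t,T_s)
            self_logit = e_tgt[i] + e_src[i]              # (N, T, 1)
            pieces = [self_logit]
            mask_pieces = [np.ones((N, T, 1), dtype=np.uint8)]
            sources = sorted(masks)
            for j in sources:
                cross = e_tgt[i] + e_src[j].swapaxes(-1, -2)  # (N, T_t, T_s)
                pieces.append(cross)
                mj = np.swapaxes(masks[j], -1, -2)   # -> (*, T_t, T_s)
                if mj.shape[0] == 1:
                    mj = np.broadcast_to(mj, (N, T, T))
                mask_pieces.append(mj)
            logits = ad.leaky_relu(ad.concat(pieces, axis=-1),
                                   cfg.leaky_slope)
            mask = np.concatenate(mask_pieces, axis=-1)
            if cfg.self_in_softmax or len(sources) == 0:
                alpha = ad.masked_softmax(logits, mask, axis=-1)
                layer_alpha.append((alpha.data, sources))
                z = alpha[:, :, 0:1] * lifted[i]
                col = 1
                for j in sources:
                    z = z + ad.matmul(alpha[:, :, col:col + T], lifted[j])
                    col += T
            else:
                alpha = ad.masked_softmax(logits[:, :, 1:], mask[:, :, 1:],
                                          axis=-1)
                layer_alpha.append((alpha.data, sources))
                z = lifted[i]
                col = 0
                for j in sources:
                    z = z + ad.matmul(alpha[:, :, col:col + T], lifted[j])
                    col += T
            outputs.append(ad.elu(z) if cfg.out_activation == "elu"
                           else ad.tanh(z) if cfg.out_activation == "tanh"
                           else z)
        return outputs

    def _check_input(self, x) -> Tensor:
        cfg = self.config
        x = np.asarray(x, dtype=cfg.dtype)
        if x.ndim != 3 or x.shape[1:] != (cfg.seq_len, cfg.feat_dim):
            raise ConfigError(
                f"input shape {x.shape} does not match config "
                f"(T={cfg.seq_len}, d={cfg.feat_dim})")
        bad = ~np.isfinite(x).all(axis=(1, 2))
        if bad.any():
            raise ValueError(
                f"non-finite input at sample index {int(np.where(bad)[0][0])}")
        return Tensor(x)

    def forward(self, x) -> list[Tensor]:
        """Class scores per task.

        ``x`` is one (N, T, d) array shared by every task's encoder, or
        a list with one such array per task.
        """
        cfg = self.config
        if isinstance(x, (list, tuple)):
            if len(x) != cfg.num_tasks:
                raise ConfigError("need one input array per task")
            xts = [self._check_input(a) for a in x]
        else:
            xts = [self._check_input(x)] * cfg.num_tasks
        self.last_adjacency = []
        self.last_attention = []
        feats = [self._encode(xts[i], i) for i in range(cfg.num_tasks)]
        for layer in range(cfg.num_layers):
            fused = [self._self_attention(feats[i], layer, i)
                     for i in range(cfg.num_tasks)]
            gw, gb = self.params[f"g{layer}_w"], self.params[f"g{layer}_b"]
            shared = [ad.matmul(c, gw) + gb for c in fused]
            feats = self._gat(shared, layer)
        N = xts[0].shape[0]
        scores = []
        for i, c in enumerate(cfg.task_classes):
            flat = feats[i].reshape(N, cfg.seq_len * cfg.gat_dim)
            scores.append(ad.matmul(flat, self.params[f"head{i}_w"])
                          + self.params[f"head{i}_b"])
        return scores

    # ------------------------------------------------------------------
    # losses
    # ------------------------------------------------------------------

    def task_loss(self, scores: Tensor, labels: np.ndarray) -> Tensor:
        """Cross-entropy of one task; labels are 1-based class ids."""
        labels = np.asarray(labels)
        c = scores.shape[-1]
        if labels.min() < 1 or labels.max() > c:
            raise ValueError(
                f"labels must lie in [1..{c}], got range "
                f"[{labels.min()}..{labels.max()}]")
        onehot = np.eye(c, dtype=scores.data.dtype)[labels - 1]
        logp = ad.log_softmax(scores, axis=-1)
        nll = -(Tensor(onehot) * logp).sum(axis=-1)
        return nll.mean() if self.config.loss_reduction == "mean" \
            else nll.sum()

    def total_loss(self, per_task: list[Tensor],
                   weights=None) -> Tensor:
        weights = self.config.loss_weights if weights is None else weights
        if len(per_task) != len(weights):
            raise ConfigError("loss/weight length mismatch")
        if any(w < 0 for w in weights):
            raise ConfigError("loss weights must be non-negative")
        total = per_task[0] * weights[0]
        for lo, w in zip(per_task[1:], list(weights)[1:]):
            total = total + lo * w
        return total

    def loss(self, x: np.ndarray, ys: list[np.ndarray]) -> Tensor:
        scores = self.forward(x)
        return self.total_loss([self.task_loss(s, y)
                                for s, y in zip(scores, ys)])

    def predict_proba(self, x: np.ndarray) -> list[np.ndarray]:
        """Per-task (N, c_i) class probabilities (no gradient tracking)."""
        scores = self.forward(x)
        out = []
        for s in scores:
            z = s.data - s.data.max(axis=-1, keepdims=True)
            e = np.exp(z)
            out.append(e / e.sum(axis=-1, keepdims=True))
        return out

    # ------------------------------------------------------------------
    # checkpoints
    # ------------------------------------------------------------------

    def save(self, path: str) -> None:
        """Archive: config JSON + parameter arrays; exact round trip."""
        cfg = {k: (list(v) if isinstance(v, (list, tuple)) else v)
               for k, v in self.config.__dict__.items()}
        buf = io.BytesIO()
        np.savez(buf, **{k: p.data for k, p in self.params.items()})
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("config.json", json.dumps(cfg))
            zf.writestr("params.npz", buf.getvalue())

    @classmethod
    def load(cls, path: str) -> "GMTLNetwork":
        with zipfile.ZipFile(path) as zf:
            cfg = ModelConfig(**json.loads(zf.read("config.json")))
            arrays = np.load(io.BytesIO(zf.read("params.npz")))
            net = cls(cfg)
            for k in net.params:
                net.params[k].data = arrays[k]
        return net


def adjacency_edge_frame(net: GMTLNetwork, sample: int = 0):
    """Edge list of the last forward pass as a DataFrame.

    Columns: layer, source_task, s, target_task, t (1-based tasks and
    timesteps) for the given sample index.
    """
    import pandas as pd

    rows = []
    for layer, per_target in enumerate(net.last_adjacency):
        for i, masks in enumerate(per_target):
            for j, mask in sorted(masks.items()):
                m = mask[0] if mask.shape[0] == 1 else mask[sample]
                for s_idx, t_idx in zip(*np.nonzero(m)):
                    rows.append({"layer": layer + 1, "source_task": j + 1,
                                 "s": int(s_idx) + 1, "target_task": i + 1,
                                 "t": int(t_idx) + 1})
    return pd.DataFrame(rows)


def attention_edge_frame(net: GMTLNetwork, sample: int = 0):
    """GAT attention coefficients of the last forward pass, long form.

    One row per (layer, target task, target timestep, source), where
    the source is either the node itself (source_task == target_task,
    s == t) or a cross-task node; ``alpha`` values over each target
    node's neighbourhood sum to 1 when the self node shares the
    softmax.
    """
    import pandas as pd

    T = net.config.seq_len
    include_self = net.config.self_in_softmax
    rows = []
    for layer, per_target in enumerate(net.last_attention):
        for i, (alpha, sources) in enumerate(per_target):
            a = alpha[sample]
            col = 1 if (include_self or not sources) else 0
            if col == 1:
                for t in range(T):
                    rows.append({"layer": layer + 1, "target_task": i + 1,
                                 "t": t + 1, "source_task": i + 1,
                                 "s": t + 1, "alpha": float(a[t, 0])})
            for j in sources:
                block = a[:, col:col + T]          # (T_target, T_source)
                for t_idx, s_idx in zip(*np.nonzero(block)):
                    rows.append({"layer": layer + 1, "target_task": i + 1,
                                 "t": int(t_idx) + 1, "source_task": j + 1,
                                 "s": int(s_idx) + 1,
                                 "alpha": float(block[t_idx, s_idx])})
                col += T
    return pd.DataFrame(rows)
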
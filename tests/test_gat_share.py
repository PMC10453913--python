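"""Graph-attention sharing: logits, normalisation, aggregation and the
full layer against scalar references."""

import math

import numpy as np
import pytest

from gmtl.gat_share import (GatParams, aggregate_node, attention_logit,
                            gat_layer, normalize_attention)
from gmtl.graph_builder import (build_causal_topk, complete_graph,
                                same_timestep_graph)
from gmtl.intra_attention import FeatureSequence


def params_identity(d, slope=0.01):
    return GatParams(np.eye(d), np.zeros(2 * d), leaky_slope=slope,
                     out_activation="identity")


class TestAttentionLogit:
    def test_zero_vector_gives_zero(self, rng):
        p = params_identity(3)
        assert attention_logit(rng.standard_normal(3),
                               rng.standard_normal(3), p) == 0.0

    def test_coordinate_selector(self):
        a = np.zeros(4)
        a[0] = 1.0
        p = GatParams(np.eye(2), a)
        assert attention_logit(np.array([5.0, 0.0]),
                               np.array([-3.0, 7.0]), p) == pytest.approx(5.0)

    def test_leaky_negative_side(self):
        a = np.zeros(4)
        a[0] = 1.0
        p = GatParams(np.eye(2), a, leaky_slope=0.01)
        out = attention_logit(np.array([-2.0, 0.0]), np.zeros(2), p)
        assert out == pytest.approx(-0.02)

    def test_length_mismatch_raises(self):
        p = params_identity(3)
        with pytest.raises(ValueError, match="length d"):
            attention_logit(np.zeros(2), np.zeros(3), p)


class TestNormalizeAttention:
    def test_self_only(self):
        out = normalize_attention({}, 1.7)
        assert out == {"self": pytest.approx(1.0)}

    def test_two_equal_logits(self):
        out = normalize_attention({(2, 0): 0.3}, 0.3)
        assert out["self"] == pytest.approx(0.5)
        assert out[(2, 0)] == pytest.approx(0.5)

    def test_log_two_softmax(self):
        out = normalize_attention({(2, 1): math.log(2.0)}, 0.0)
        assert out["self"] == pytest.approx(1 / 3)
        assert out[(2, 1)] == pytest.approx(2 / 3)

    def test_coefficients_sum_to_one(self, rng):
        logits = {(2, s): rng.standard_normal() for s in range(5)}
        out = normalize_attention(logits, rng.standard_normal())
        assert sum(out.values()) == pytest.approx(1.0, abs=1e-6)

    def test_literal_reading_keeps_unit_self_weight(self):
        out = normalize_attention({(2, 0): 0.0, (2, 1): 0.0}, 5.0,
                                  include_self=False)
        assert out["self"] == 1.0
        assert out[(2, 0)] == pytest.approx(0.5)


class TestAggregateNode:
    def test_no_neighbors_returns_lifted_target(self, rng):
        w = rng.standard_normal((3, 2))
        p = GatParams(w, np.zeros(4))
        target = rng.standard_normal(3)
        np.testing.assert_allclose(aggregate_node(target, [], 1.0, p),
                                   target @ w, atol=1e-12)

    def test_identical_neighbors_fixed_point(self, rng):
        w = rng.standard_normal((3, 3))
        p = GatParams(w, np.zeros(6))
        target = rng.standard_normal(3)
        z = aggregate_node(target, [(target, 0.3), (target, 0.5)], 0.2, p)
        np.testing.assert_allclose(z, target @ w, atol=1e-12)

    def test_convex_combination(self):
        p = params_identity(2)
        z = aggregate_node(np.array([4.0, 0.0]),
                           [(np.array([0.0, 4.0]), 0.75)], 0.25, p)
        np.testing.assert_allclose(z, [1.0, 3.0], atol=1e-12)

    def test_unnormalised_coefficients_rejected(self):
        p = params_identity(2)
        with pytest.raises(ValueError, match="sum to 1"):
            aggregate_node(np.zeros(2), [(np.ones(2), 0.4)], 0.4, p)


def scalar_gat_reference(feats, adjacencies, p):
    """Fully scalar per-node recomputation of one GAT layer."""
    by_task = {f.task_id: f.values for f in feats}
    T, d = feats[0].values.shape
    dp = p.weight.shape[1]
    outs = []
    for f, adj in zip(feats, adjacencies):
        rows = np.zeros((T, dp))
        for t in range(T):
            tgt = f.values[t]
            wt = np.array([sum(tgt[a] * p.weight[a, b] for a in range(d))
                           for b in range(dp)])
            neigh = []
            for j, mask in sorted(adj.mask.items()):
                for s in range(T):
                    if mask[s, t]:
                        src = by_task[j][s]
                        ws = np.array([sum(src[a] * p.weight[a, b]
                                           for a in range(d))
                                       for b in range(dp)])
                        pre = sum(p.attn_vector[b] * wt[b] for b in range(dp))
                        pre += sum(p.attn_vector[dp + b] * ws[b]
                                   for b in range(dp))
                        beta = pre if pre > 0 else p.leaky_slope * pre
                        neigh.append((ws, beta))
            pre_self = sum(p.attn_vector[b] * wt[b] for b in range(dp))
            pre_self += sum(p.attn_vector[dp + b] * wt[b] for b in range(dp))
            b_self = pre_self if pre_self > 0 else p.leaky_slope * pre_self
            logits = [b_self] + [b for _, b in neigh]
            m = max(logits)
            exps = [math.exp(b - m) for b in logits]
            z = sum(exps)
            alphas = [e / z for e in exps]
            agg = alphas[0] * wt
            for (ws, _), a in zip(neigh, alphas[1:]):
                agg = agg + a * ws
            rows[t] = p.activate(agg)
        outs.append(rows)
    return outs


def random_instance(rng, M=2, T=4, d=3, frac=0.5, activation="elu"):
    feats = [FeatureSequence(rng.standard_normal((T, d)), task_id=i + 1,
                             stage="shared") for i in range(M)]
    adjacencies = []
    for i in range(M):
        sims = {}
        for j in range(M):
            if j != i:
                sims[j + 1] = rng.standard_normal((T, T))
        adjacencies.append(build_causal_topk(sims, frac, target_task=i + 1))
    p = GatParams(rng.standard_normal((d, d)),
                  rng.standard_normal(2 * d), out_activation=activation)
    return feats, adjacencies, p


class TestGatLayer:
    def test_single_task_reduces_to_lifted_self(self, rng):
        f = FeatureSequence(rng.standard_normal((4, 3)), task_id=1,
                            stage="shared")
        p = GatParams(rng.standard_normal((3, 3)), rng.standard_normal(6))
        out = gat_layer([f], [complete_graph(4, 1, 1)], p)[0]
        np.testing.assert_allclose(out.values, p.activate(f.values @ p.weight),
                                   atol=1e-12)

    def test_constant_features_give_constant_output(self, rng):
        vals = np.tile(rng.standard_normal(3), (5, 1))
        feats = [FeatureSequence(vals.copy(), task_id=i + 1, stage="shared")
                 for i in range(2)]
        adjs = [complete_graph(5, 2, 1), complete_graph(5, 2, 2)]
        p = GatParams(rng.standard_normal((3, 3)), rng.standard_normal(6))
        for out in gat_layer(feats, adjs, p):
            np.testing.assert_allclose(out.values,
                                       np.tile(out.values[0], (5, 1)),
                                       atol=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_scalar_reference(self, seed):
        rng = np.random.default_rng(seed)
        feats, adjs, p = random_instance(rng, M=2, T=4, d=3)
        out = gat_layer(feats, adjs, p)
        ref = scalar_gat_reference(feats, adjs, p)
        for o, r in zip(out, ref):
            np.testing.assert_allclose(o.values, r, atol=1e-6)

    def test_masking_fidelity(self, rng):
        """Nodes outside the adjacency get exactly zero weight."""
        feats, adjs, p = random_instance(rng, M=2, T=5, d=3, frac=0.3)
        out = gat_layer(feats, adjs, p)
        mask = adjs[0].mask[2]
        s_out, t_out = np.where(mask == 0)
        # perturb a non-neighbour feature of task 2 and recompute task 1
        feats2 = [FeatureSequence(f.values.copy(), task_id=f.task_id,
                                  stage="shared") for f in feats]
        s = s_out[0]
        feats2[1].values[s] += 100.0
        out2 = gat_layer(feats2, adjs, p)
        cols_untouched = [t for t in range(5) if mask[s, t] == 0]
        np.testing.assert_allclose(out2[0].values[cols_untouched],
                                   out[0].values[cols_untouched], atol=1e-10)

    def test_same_timestep_neighbourhood(self, rng):
        """With the co-temporal graph, node t sees only itself and the
        other task's node t."""
        feats, _, p = random_instance(rng, M=2, T=4, d=3)
        adjs = [same_timestep_graph(4, 2, 1), same_timestep_graph(4, 2, 2)]
        out = gat_layer(feats, adjs, p)
        feats2 = [FeatureSequence(f.values.copy(), task_id=f.task_id,
                                  stage="shared") for f in feats]
        feats2[1].values[2] += 50.0  # only target node 2 may change
        out2 = gat_layer(feats2, adjs, p)
        changed = np.abs(out2[0].values - out[0].values).max(axis=1) > 1e-12
        np.testing.assert_array_equal(changed,
                                      [False, False, True, False])

    def test_out_of_range_adjacency_raises(self, rng):
        feats, adjs, p = random_instance(rng, M=2, T=4, d=3)
        adjs[0].mask[2] = np.zeros((6, 6), dtype=np.uint8)
        adjs[0].mask[2][5, 5] = 1
        with pytest.raises(IndexError):
            gat_layer(feats, adjs, p)
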
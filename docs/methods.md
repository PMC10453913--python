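# Methods

## The model

`gmtl` implements a multi-task time-series classifier for panels of the
form X ∈ R^(N×T×d) (N samples, T timesteps, d features) with one
binary — or small-cardinality categorical — label per task per sample.
The motivating setting is clinical risk prediction from ICU time
series, where the feature trajectory that signals one outcome (say,
fever) at an early timestep carries information about a related outcome
(say, mortality) at a later timestep. The architecture captures two
kinds of temporal structure:

**Global intra-task dependencies.** Each task i has its own 2-layer
LSTM encoder producing per-timestep hidden states F ∈ R^(T×h). Within
each of L stacked sharing layers, a task-specific self-attention block
computes Q = Q(F), K = K(F), V = V(F) (linear maps with bias) and

    C = F + softmax(Q Kᵀ) V,

an unmasked attention over all T timesteps with a residual fusion. The
score matrix is deliberately *not* scaled by 1/√d — that is how the
model is defined — but `scaled_attention: true` switches on the
conventional temperature for large d.

**Local inter-task dependencies.** Fused features are mapped into a
task-shared space, C̃ = G(C), by a linear map shared across tasks
within a layer. For every ordered task pair (j → i) the cosine
similarity μ[s, t] between C̃ⱼ at timestep s and C̃ᵢ at timestep t is
computed per sample. A directed graph over (task, timestep) nodes keeps
only causal candidates (s ≤ t) and, per target node t and per source
task, the K most similar sources with

    K = min(max(1, ceil(topk_fraction · t)), t),   t counted 1-based.

The `max(1, ·)` floor guarantees every target node keeps at least one
inbound edge per source task, so early timesteps are never isolated;
ties in μ break toward the earlier source timestep for determinism.
The adjacency is recomputed per sample and per layer inside the forward
pass — it is a function of the instance's features, not a learned
global parameter. Selection is hard: gradients flow through the
attention weights on selected edges and through C̃, not through the
TopK choice itself.

Aggregation is single-head graph attention. With a layer-shared lift
W : R^d → R^d' and attention vector a ∈ R^(2d'),

    β(t, s) = LeakyReLU(aᵀ [W C̃ᵢₜ ‖ W C̃ⱼₛ]),
    α       = softmax over {self} ∪ {neighbours with A = 1},
    Zₜ      = α_self W C̃ᵢₜ + Σ α(s) W C̃ⱼₛ,
    fₜ      = σ(Zₜ),

with σ = ELU by default. The self node participates in the same
softmax as the neighbours (the standard graph-attention convention;
`self_in_softmax: false` selects the literal alternative in which the
softmax runs over neighbours only and the self term has unit weight).
The layer output f feeds the next sharing layer as its input; after L
layers the T outputs are concatenated and a per-task linear head with a
softmax gives class probabilities.

**Loss.** Per-task categorical cross-entropy, averaged over the batch
(so per-task weights λᵢ are comparable across datasets of different
size; `loss_reduction: sum` restores the literal summed form), combined
as Σ λᵢ Lᵢ with λᵢ = 1 by default. Labels are 1-based externally
(y ∈ {1, …, cᵢ}) and shifted to 0-based indices at the loss boundary.

## Variants

* `full` — the model proper: learned causal TopK graph.
* `complete_graph` — the graph replaced by the fixed causal complete
  graph (every s ≤ t). Read literally, "connecting all nodes to the
  current node" is causal-complete; `causal_complete: false` lifts the
  constraint for comparison. With `topk_fraction: 1.0` the full
  variant reproduces this variant bit for bit.
* `no_intra_attention` — the temporal attention weights replaced by
  uniform 1/T.
* `same_timestep` — sharing restricted to co-temporal nodes (s = t).
* `non_shared` — the empty cross-task graph. The GAT then reduces to
  the self node, f = σ(W G(C)), so the tasks train jointly but exchange
  nothing. This reading (rather than bypassing the graph stage
  entirely) is the one under which a single-task `full` model and the
  `non_shared` path coincide exactly, which we treat as the defining
  property of "no feature sharing".

## Defaults and units

| parameter | default | meaning |
|---|---|---|
| `lr` | 0.001 | Adam learning rate |
| `epochs` | 600 | full-protocol training length |
| `batch_size` | 256 | samples per gradient step |
| `encoder_layers` | 2 | LSTM depth per task |
| `encoder_hidden` | 32 | LSTM width h (= working d of the sharing layers) |
| `num_layers` | 2 | stacked sharing layers L |
| `topk_fraction` | 0.20 | kept fraction of causal candidate edges |
| `leaky_slope` | 0.01 | LeakyReLU slope in β (graph-attention literature often uses 0.2; configurable) |
| `gat_dim` | = `encoder_hidden` | d', kept equal so layers chain without projection |
| `seeds` | 5 | independent runs per reported mean ± SE |

Weights use fan-based uniform (Glorot) initialisation drawn from a
generator seeded by `ModelConfig.seed`, so a configuration fully
determines a model instance. LSTM forget-gate biases start at 1.
Training is exactly reproducible: the same config and seed give
bit-identical traces on a given platform.

## Numerical core

The network runs on a small reverse-mode automatic-differentiation
engine over numpy arrays (`gmtl._autodiff`): broadcast-aware
arithmetic, batched matmul, masked softmax (disallowed entries receive
exactly zero weight and pass no gradient), and the usual
nonlinearities. The LSTM layer is a single fused graph node with a
hand-written backpropagation-through-time. Gradients are verified
against central finite differences in the test suite. Arrays are
float64 by default; `dtype: float32` halves memory traffic and is used
for the desk-scale benchmark. Zero-norm rows in the shared space would
make the cosine undefined; their similarities are defined as 0 (never
preferred over genuine correlations) with a warning.

## Synthetic data

Real ICU extracts of the kind this model targets are access-controlled,
so the package ships a generator that emulates their statistical
skeleton rather than their clinical content. Per sample, `latent_dim`
(default 4) independent AR(1) processes z_t = φ z_{t−1} + ε with
φ = 0.9 and unit stationary variance mimic smooth physiological
dynamics. Observations are a fixed random linear mixing of z plus
Gaussian noise (σ = 1.0 — observed features are as noisy as the signal
they carry). Task 1's label is Bernoulli(sigmoid(effect · u + b)) with
u the standardised projection of the latent mean over an early window
(length 4); each later task uses the same shared latent direction over
a window shifted `cross_task_lag` (default 4) steps later, mixed with
a task-specific latent direction (shared fraction 0.8). Task i's
outcome is therefore partly predictable from the features most
relevant to task i−1 at strictly earlier timesteps — the causal
cross-task dependency the sharing mechanism exploits — and shuffling
those upstream features across samples demonstrably destroys it.
Intercepts are calibrated by root finding so realized positive rates
hit their targets (defaults 0.35/0.25/0.15, decreasing with outcome
severity as in clinical event data); `effect_size` = 2.0 puts the
Bayes-oracle AUROC near 0.85–0.88.

Default dimensions mirror a published ICU extract scale
(1921 × 48 × 12, 3 tasks). What the generator does *not* emulate:
missingness and irregular sampling, variable-specific marginals
(heart rate, blood pressures, …), nonstationarity, and task labels
with any structure beyond the logistic-latent construction. Passing
tests therefore demonstrate that the implementation recovers planted
dependence of this specific kind, not clinical performance.

## Desk-scale benchmark

`gmtl.benchmark` fixes one CPU-friendly configuration used by the test
suite and the reproduction script: generator at n = 1000, T = 24,
d = 8, M = 3, lag 4; a 750/250 split; a 16-unit float32 model with
L = 2; 50 epochs of Adam at the default learning rate and batch size;
five seeds per variant on the identical split. These sizes are the
package's chosen desk-scale study conditions; the full-protocol
defaults (600 epochs, width 32, float64) remain available through the
configuration. The headline comparison is mean held-out AUROC on task
3 — the most-downstream task — for `full` vs `same_timestep` vs
`non_shared`.

Two remarks on what this benchmark can and cannot show. First, the
input panel X is shared by all tasks, so every task's encoder sees all
information in principle; any benefit of sharing here is borrowed
statistical strength (task 3 has the rarest outcome), not access to
otherwise-hidden features. Cross-timestep sharing does beat
same-timestep-only sharing on the downstream task, but against the
non-shared variant the measured gain is small and can be negative:
with redundant inputs, the near-uniform initial graph attention
dilutes each node's own features (the self weight starts near
1/(1+K)), a mild negative-transfer effect that 50 epochs do not fully
undo. Multi-task degradation of individual tasks is a known
phenomenon in this setting and is visible here. Second, 50 epochs at
n = 750 is far short of the full protocol; directional comparisons
between variants on the common split are meaningful, absolute AUROCs
are not.

## Known limitations

* Fixed T per model; no padding/masking for variable-length stays.
* Binary/categorical outcomes only; no regression heads.
* Single-head attention throughout (both attention stages).
* The TopK selection is non-differentiable; graphs with learnable
  soft sparsity are out of scope.
* CPU-only numpy execution: desk-scale by design.
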
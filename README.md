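# gmtl — graph-based multi-task time-series forecasting

`gmtl` jointly trains several related classifiers on multivariate time
series — the motivating case is clinical risk prediction from ICU
vitals, where tasks such as *fever*, *infection* and *mortality* are
temporally linked: features that signal one outcome early carry
information about another outcome later. It is written for
researchers who want a transparent, CPU-only, fully reproducible
implementation of cross-timestep feature sharing to study, ablate and
extend.

## The model

Given panels X ∈ R^(N×T×d) and one label per task per sample, each
task i gets a 2-layer LSTM encoder, followed by L stacked sharing
layers that capture two kinds of dependency:

* **global, intra-task** — unmasked self-attention over a task's own
  timesteps with residual fusion:
  C = F + softmax(Q Kᵀ) V;
* **local, inter-task** — a directed graph over (task, timestep)
  nodes, learned per sample from cosine similarities of shared-space
  features C̃ = G(C). Only causal edges (source timestep s ≤ target
  timestep t) are candidates, and per target node and source task the
  TopK most similar ones survive, K = max(1, ⌈fraction · t⌉). A graph
  attention layer then aggregates each node with its selected
  neighbours, β = LeakyReLU(aᵀ[W C̃ᵢₜ ‖ W C̃ⱼₛ]), α = softmax over
  {self} ∪ neighbours, f = σ(α_self W C̃ᵢₜ + Σ α W C̃ⱼₛ).

The T outputs are concatenated into a per-task linear head; training
minimises Σᵢ λᵢ · CE(ŷᵢ, yᵢ) with Adam (defaults: lr 0.001, 600
epochs, batch 256, TopK 20%). Ablation variants — fixed complete
graph, uniform temporal attention, same-timestep-only sharing, and no
sharing at all — are selectable through one config field. See
`docs/methods.md` for the full account, including the synthetic
generator that stands in for access-controlled ICU extracts.

## Worked example

```python
from gmtl import GMTLModel, benchmark_spec, generate

batch, _ = generate(benchmark_spec(seed=0))   # 1000 x 24 x 8, 3 tasks
train_set, test_set = batch.split(750, seed=0)

model = GMTLModel(train_set, encoder_hidden=16, num_layers=2,
                  dtype="float32", seed=0)
result = model.fit(epochs=50, log_every=0)
print(result.summary())
print("held-out AUROC per task:",
      [round(float(a), 4) for a in result.auroc(test_set)])
```

prints

```
G-MTL: cross-timestep feature-sharing multi-task forecaster
============================================================
variant:          full
tasks / T / d:    3 / 24 / 8
encoder:          2-layer LSTM, hidden 16
sharing layers:   2  (TopK fraction 0.20)
parameters:       19462
epochs trained:   50  (lr 0.001, batch 256)
final loss:       0.98977
------------------------------------------------------------
task_1 train AUROC:  0.9015
task_2 train AUROC:  0.8721
task_3 train AUROC:  0.8954
average train AUROC: 0.8897
============================================================
held-out AUROC per task: [0.7516, 0.8059, 0.8016]
```

The three tasks share one latent AR(1) process whose relevance window
shifts 4 steps later from task to task, so task 3 is the most
downstream outcome. Train AUROC near 0.89 against held-out AUROC near
0.78 shows the small model starting to memorise, and the held-out
numbers sit below the generator's Bayes-oracle ceiling of roughly
0.88. Variant comparisons (`gmtl.training.compare_variants`, or
`gmtl ablate` on the command line) report per-task mean ± standard
error over seeds on a common split.

A CLI covers the common workflows:

```bash
gmtl generate --out data/ --seed 0        # synthetic dataset (CSV + sidecar)
gmtl train --config run.yaml --out run/   # checkpoint + loss trace
gmtl ablate --config run.yaml --out abl/  # 4-variant comparison table
gmtl sweep --topk 10,15,20,25,30,35,40 --config run.yaml --out sweep/
```

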
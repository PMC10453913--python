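"""Desk-scale benchmark: sharing benefit on the planted-signal generator.

One CPU-friendly configuration used throughout the test suite and the
reproduction script: the synthetic generator at n=1000, T=24, d=8,
M=3, lag 4 (see :func:`gmtl.config.benchmark_spec`), a 16-unit
single-precision model, a fixed 750/250 split, 50 epochs, and five
seeds per variant.  The quantity of interest is the mean test AUROC on
the last task — the one whose outcome window sits furthest downstream
of the shared latent signal — compared across the full model, the
same-timestep-only sharing ablation, and the non-shared variant.
"""

from __future__ import annotations

from .config import ModelConfig, TrainSpec, benchmark_spec
from .synthetic import generate
from .training import EvalReport, compare_variants

BENCHMARK_VARIANTS = ("full", "same_timestep", "non_shared")


def benchmark_config(seed: int = 0, **overrides) -> ModelConfig:
    """Desk-scale model configuration matching the benchmark generator."""
    fields = dict(num_tasks=3, seq_len=24, feat_dim=8, encoder_hidden=16,
                  num_layers=2, dtype="float32", seed=seed)
    fields.update(overrides)
    return ModelConfig(**fields)


def benchmark_train_spec(epochs: int = 50,
                         seeds=(0, 1, 2, 3, 4)) -> TrainSpec:
    return TrainSpec(epochs=epochs, seeds=list(seeds), log_every=0)


def run_benchmark(data_seed: int = 0, epochs: int = 50,
                  seeds=(0, 1, 2, 3, 4),
                  variants=BENCHMARK_VARIANTS) -> EvalReport:
    """Train each variant across seeds on one shared split; report AUROC."""
    batch, _ = generate(benchmark_spec(seed=data_seed))
    return compare_variants(batch, list(variants), benchmark_config(),
                            benchmark_train_spec(epochs, seeds),
                            n_train=750, split_seed=data_seed)


def lag_task_auroc(report: EvalReport, variant: str) -> float:
    """Mean test AUROC of the most-downstream task for one variant."""
    t = report.table
    row = t[(t["variant"] == variant) & (t["task"] == "task_3")]
    return float(row["auroc_mean"].iloc[0])
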
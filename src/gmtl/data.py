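"""The Batch container: multivariate sequences + per-task labels."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _check_x(x: np.ndarray, n: int | None = None) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 3:
        raise ValueError("x must have shape (N, T, d)")
    if n is not None and x.shape[0] != n:
        raise ValueError("per-task inputs must share the sample count N")
    if not np.isfinite(x).all():
        raise ValueError("x contains non-finite entries")
    return x


@dataclass
class Batch:
    """Training/evaluation unit.

    x : (N, T, d) float array shared across tasks (the default), or a
        list of one such array per task.
    y : list over tasks of length-N integer label vectors, 1-based
        (values in 1..c_i).
    task_classes : classes per task; inferred as binary when omitted.
    """

    x: np.ndarray | list[np.ndarray]
    y: list[np.ndarray]
    task_classes: list[int] = field(default_factory=list)

    def __post_init__(self):
        if isinstance(self.x, (list, tuple)):
            first = _check_x(self.x[0])
            self.x = [first] + [_check_x(a, first.shape[0])
                                for a in self.x[1:]]
            if len(self.x) != len(self.y):
                raise ValueError("need one input array per task")
        else:
            self.x = _check_x(self.x)
        self.y = [np.asarray(yy, dtype=int) for yy in self.y]
        if not self.task_classes:
            self.task_classes = [max(2, int(yy.max())) for yy in self.y]
        n = self.n_samples
        for i, (yy, c) in enumerate(zip(self.y, self.task_classes)):
            if yy.shape != (n,):
                raise ValueError(f"task {i + 1} labels must have length N={n}")
            if yy.min() < 1 or yy.max() > c:
                raise ValueError(
                    f"task {i + 1} labels outside [1..{c}]: "
                    f"range [{yy.min()}..{yy.max()}]")

    @property
    def n_samples(self) -> int:
        return (self.x[0] if isinstance(self.x, list) else self.x).shape[0]

    @property
    def num_tasks(self) -> int:
        return len(self.y)

    def subset(self, idx: np.ndarray) -> "Batch":
        xs = [a[idx] for a in self.x] if isinstance(self.x, list) \
            else self.x[idx]
        return Batch(xs, [yy[idx] for yy in self.y], list(self.task_classes))

    def split(self, n_train: int, seed: int = 0) -> tuple["Batch", "Batch"]:
        """One shuffled train/test split, shared across model variants."""
        if not (0 < n_train < self.n_samples):
            raise ValueError("n_train must be in (0, N)")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(self.n_samples)
        return self.subset(perm[:n_train]), self.subset(perm[n_train:])
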
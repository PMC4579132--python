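"""Three-class 3-D toy data generator.

Each class c draws samples as ``mean_c + scale_c * x`` with ``x`` i.i.d.
uniform on (0, 1) per coordinate, giving three overlapping non-negative
point clouds.  The defaults reproduce the standard small benchmark used to
illustrate label propagation: class means [1, 0.8, 0.8], [0.8, 0.8, 0.8]
and [0.8, 1, 0.7] with noise scales 0.1, 0.1, 0.15, ten samples per class
of which three are labeled (30 samples, 9 labeled, 21 unlabeled).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import UNLABELED, ExpressionMatrix, PartialLabelSet

__all__ = ["ToySpec", "generate_toy"]

_DEFAULT_MEANS = ((1.0, 0.8, 0.8), (0.8, 0.8, 0.8), (0.8, 1.0, 0.7))
_DEFAULT_SCALES = (0.1, 0.1, 0.15)


@dataclass
class ToySpec:
    """Parameters of the toy generator; defaults are the benchmark values."""

    means: tuple = _DEFAULT_MEANS
    noise_scales: tuple = _DEFAULT_SCALES
    n_per_class: int = 10
    n_labeled_per_class: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        self.means = tuple(tuple(float(x) for x in m) for m in self.means)
        self.noise_scales = tuple(float(s) for s in self.noise_scales)
        if len(self.means) != len(self.noise_scales):
            raise ValueError("one noise scale per class mean is required")
        if any(s <= 0 for s in self.noise_scales):
            raise ValueError("noise scales must be positive")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be positive")
        if not 0 <= self.n_labeled_per_class <= self.n_per_class:
            raise ValueError("n_labeled_per_class must be in [0, n_per_class]")


def generate_toy(
    spec: ToySpec | None = None,
) -> tuple[ExpressionMatrix, PartialLabelSet, np.ndarray]:
    """Generate the toy dataset.

    Returns the expression matrix (samples × 3 coordinates), the partial
    label set (the first ``n_labeled_per_class`` samples of each class are
    labeled, the rest unlabeled; samples are i.i.d. within a class so this
    selection is exchangeable), and the ground-truth class index of every
    sample.  The same seed reproduces the dataset bit for bit.
    """
    if spec is None:
        spec = ToySpec()
    rng = np.random.default_rng(spec.seed)
    r = len(spec.means)

    blocks, truth, assign = [], [], []
    for c, (mean, scale) in enumerate(zip(spec.means, spec.noise_scales)):
        x = rng.uniform(size=(spec.n_per_class, len(mean)))
        blocks.append(np.asarray(mean)[None, :] + scale * x)
        truth.extend([c] * spec.n_per_class)
        assign.extend(
            [c] * spec.n_labeled_per_class
            + [UNLABELED] * (spec.n_per_class - spec.n_labeled_per_class)
        )

    values = np.vstack(blocks)
    n = values.shape[0]
    data = ExpressionMatrix(
        values=values,
        sample_ids=[f"s{i}" for i in range(n)],
        gene_ids=[f"dim{j}" for j in range(values.shape[1])],
    )
    labels = PartialLabelSet(
        classes=[f"class{c}" for c in range(r)],
        assignment=np.asarray(assign, dtype=int),
    )
    return data, labels, np.asarray(truth, dtype=int)
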
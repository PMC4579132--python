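"""Condition a raw microarray-style table: bound, impute, filter.

Builds a small synthetic intensity matrix with a few missing probes,
clamps values into the [20, 16000] box, fills the missing entries by
gene-axis k-NN averaging, and drops genes whose across-sample max/min
ratio is below 5 or whose max−min variation is below 500.
"""

import numpy as np

from semipnmf import ExpressionMatrix, bound_expression, filter_genes, knn_impute

rng = np.random.default_rng(0)
n_samples, n_genes = 20, 100
values = rng.uniform(10, 300, size=(n_samples, n_genes))
values[:, :30] *= rng.uniform(5, 60, size=(n_samples, 30))  # informative genes
mask = rng.uniform(size=values.shape) < 0.02
values[mask] = np.nan

data = ExpressionMatrix(
    values=values,
    sample_ids=[f"s{i}" for i in range(n_samples)],
    gene_ids=[f"g{j}" for j in range(n_genes)],
    allow_missing=True,
)
print(f"input: {data.n_samples} samples x {data.n_genes} genes, "
      f"{int(mask.sum())} missing entries")

data = knn_impute(data, k=5)          # fill NA from the 5 nearest genes
data = bound_expression(data, 20, 16000)
filtered, report = filter_genes(data, ratio_min=5, variation_min=500)

print(f"after imputation: {int(np.isnan(filtered.values).sum())} missing entries")
print(f"gene filter kept {report.n_after} of {report.n_before} genes")
# Kept genes vary enough across samples to carry class signal; flat genes
# (ratio < 5 or variation < 500 intensity units) are discarded.
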
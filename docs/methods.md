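# Methods

## Model and assumptions

Semi-PNMF represents every expression profile as a non-negative
combination of r shared cluster centroids, one centroid per declared
class. Its objective has three parts:

1. **Reconstruction.** `1/2 ‖[V_L; V_U] − [Q; H_U] W‖²_F`. The labeled
   block of the coefficient matrix is identically the one-hot indicator
   `Q` throughout — labeled coefficients are never free variables — so a
   labeled sample of class j is reconstructed by centroid `W[j]` alone.
   This is what makes the centroids class-aligned.
2. **Centroid consistency (α).** `α/2 ‖W − H_Uᵀ V_U‖²_F` relaxes the
   projective constraint `W = HᵀV` into a penalty, tying centroids to the
   span of the unlabeled data so the learned subspace reflects the full
   cohort, not just the labeled handful.
3. **Local coordinate penalty (β).** `β/2 Σ_ij H_U[i,j] ‖V_U[i] − W[j]‖²`
   charges each coefficient by the squared distance to the centroid it
   activates, inducing sparse, nearly one-hot coefficient rows.

Assumptions: expression values are non-negative and finite; classes are
characterised by distinct mean profiles; r equals the number of declared
classes (no independent model-order selection); every sample belongs to
exactly one class.

## Optimization

Alternating multiplicative updates, W first then H_U, each derived from a
diagonal majorizer of the objective (the classic auxiliary-function
construction), so each half-step is non-increasing in J:

```
W  ← W ⊗ [QᵀV_L + (1+α+β) H_UᵀV_U] ⊘ [QᵀQ W + H_UᵀH_U W + α W + β F_U W + g]
H_U ← H_U ⊗ [(1+α+β) V_U Wᵀ] ⊘ [H_U W Wᵀ + α V_U V_Uᵀ H_U + β/2 (A + B) + g]
```

with `F_U = diag(column sums of H_U)` (an r×r matrix — forced by the shape
of `F_U W`), `A[i,j] = ‖V_U[i]‖²`, `B[i,j] = ‖W[j]‖²` (both broadcast to
n_U×r — forced by the gradient of the local coordinate term), and `g` a
small additive denominator guard. J is evaluated on the full
three-term objective after each complete iteration; the stopping rule is
the relative change `|J_{l+1} − J_l| / |J_l| < tol`. With no labeled
samples (d = 0) the Q terms vanish and the model reduces to its
unsupervised form; this degenerate mode is supported.

Numerical choices:

- **Initialization**: W and H_U i.i.d. uniform on (0, 1) from a seeded
  generator. A strictly positive start avoids the zero-locking of
  multiplicative updates (an entry that is exactly 0 stays 0 forever,
  which the tests exercise as a property, not a defect).
- **Denominator guard**: `1e-12` added to every update denominator. The
  rules are undefined at exact zeros; the guard perturbs fixed points by
  at most guard/denominator, which the fixed-point tests bound.
- **Tie-break in prediction**: argmax ties go to the lowest class index,
  making predictions deterministic and invariant to positive rescaling of
  H_U.
- **J = 0 exactly**: iteration stops immediately with `converged=True`
  (the relative criterion is undefined there).
- **No internal normalization of V**: values are used as given after
  preprocessing; an explicit preprocessing step is the only rescaling.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.2 | weight of the centroid-consistency penalty (dimensionless) |
| `beta` | 0.01 | weight of the local coordinate penalty (dimensionless) |
| `tol` | 1e-7 | relative objective change at which iteration stops |
| `max_iter` | 1500 | iteration cap; hitting it sets `converged=False` |
| `seed` | 0 | seeds factor initialization (and per-fold seeds in CV) |
| `denom_guard` | 1e-12 | additive guard in update denominators |

α and β are dataset-dependent in practice: strong consistency (α ≈ 2 with
β ≈ 1e-4) suits heavily filtered, high-dimensional microarray panels where
the unlabeled mass should dominate the subspace, while milder settings
(α ≈ 0.2, β ≈ 0.01) behave better on low-dimensional or small-magnitude
data, where a large α overweights the `W ≈ H_UᵀV_U` pull (whose scale
grows with the number of unlabeled samples). The package defaults to the
milder pair as the safer general-purpose choice; analyses of wide
microarray panels should pass the stronger setting explicitly. No
automatic α/β tuning is provided.

## Preprocessing

- `bound_expression` clamps intensities into `[lo, hi]` (defaults 20 and
  16,000 units), removing low-end noise and high-end saturation.
  Idempotent.
- `filter_genes` keeps genes with across-sample `max/min ≥ 5` **and**
  `max − min ≥ 500` (defaults). Threshold semantics are
  keep-at-the-boundary: a gene with ratio exactly 5 survives. Requires a
  bounded matrix so per-gene minima are positive and ratios well defined.
- `knn_impute` fills a missing entry (sample i, gene g) with the mean of
  the k nearest genes' values at sample i. Neighbours live on the gene
  axis; gene–gene distance is Euclidean over co-observed samples, scaled
  by the co-observed count so partially observed pairs compare fairly.
  k defaults to 5. Delegated to `sklearn.impute.KNNImputer` on the
  transposed matrix, which implements exactly this scheme; a brute-force
  pair-enumeration oracle in the tests pins the semantics. The axis,
  metric, and k are genuinely open design choices here — nothing in the
  method constrains them — so all three are configurable.

Step order for a raw microarray table: impute (if needed) → bound →
filter.

## Evaluation harness

- Confusion matrices are tallied with rows = true class, columns =
  predicted class; one-vs-rest sensitivity `TP/(TP+FN)` and specificity
  `TN/(TN+FP)` per class. A metric with a zero denominator is reported as
  missing (NaN), never as 0, and macro averages skip missing entries.
- `run_leave_one_unlabeled`: each fold hides one sample's label, fits
  with that single sample unlabeled, and predicts it; fold f uses seed
  `base + f`. Note an intrinsic caveat: with n_U = 1 the α term ties all
  centroids to that one sample and the argmax favours larger-norm
  centroids, so this protocol is harsher than transductive use on classes
  that differ only slightly in profile norm.
- `run_labeled_count_curve`: for each labeled count c and trial t, c
  labeled samples per class are drawn without replacement from a
  generator seeded by (base seed, c, t); accuracy is measured on all
  remaining samples and averaged over trials (default 100).

Both protocols are provided because published accuracy figures for this
family of methods are reported under each; neither is silently preferred —
callers choose.

## Synthetic data

`generate_toy` emulates a 3-D, three-class benchmark: class c samples are
`mean_c + scale_c · x` with `x ~ U(0,1)³`, means `[1, 0.8, 0.8]`,
`[0.8, 0.8, 0.8]`, `[0.8, 1, 0.7]` and scales 0.1, 0.1, 0.15, ten samples
per class with the first three labeled (selection is exchangeable since
samples are i.i.d.). Classes 0 and 1 overlap in two of three coordinates,
so this is a non-trivial but solvable transductive problem. What it does
not emulate: the dimensionality (tens of thousands of genes), heavy-tailed
intensity distributions, batch effects, or class imbalance of real
expression data — passing toy tests demonstrates the mechanism (label
propagation through shared centroids), not clinical performance.
Well-separated variants (means pushed apart) are used where a test needs a
case that any sound classifier should solve perfectly.

## Problem sizes in tests and the acceptance script

Descent, oracle-equivalence, and stationarity checks run on random
instances with n ≤ 20 samples, m ≤ 10 genes, and r ≤ 4 classes across
α/β grids that include 0 — small enough to compare against scalar-loop
transcriptions of the update algebra and to enumerate exhaustively, large
enough to exercise every term. The acceptance script mirrors these sizes
and the default toy dimensions.

## Known limitations

- Convergence is to a stationary point of a non-convex objective;
  different seeds can reach different (occasionally worse) labelings. The
  toy recovery figure is therefore reported as a rate over seeds.
- The labeled coefficient block being hard-pinned to Q means label noise
  is propagated, not corrected.
- Multiplicative updates shrink but never zero out entries (and never
  revive exact zeros); sparsity in H_U is approximate.
- The default 1500-iteration cap can stop short of the `tol` criterion on
  easy problems with slowly decaying objectives; predictions are typically
  stable long before the cap.
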
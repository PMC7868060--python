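# jointlasso

Sparse high-dimensional linear regression jointly estimated over subgroups
of samples, with pairwise fusion penalties — the *joint lasso*.

## The problem

Biomedical studies increasingly span subgroups of samples — disease
subtypes, clinical stages, tissues — whose relationships between a
high-dimensional feature vector and a response are similar but not
identical. Pooling all samples into one lasso mis-specifies the model when
subgroups genuinely differ; fitting each subgroup separately throws away
the shared signal and suffers from small per-subgroup sample sizes. The
joint lasso treats the K subgroup regressions as related problem instances
and estimates them together.

With subgroup-specific design matrices `X_k` (n_k × p), responses `y_k`
(both standardized within subgroup, so no intercepts are needed) and
coefficient vectors collected in the p × K matrix `B = [β_1 … β_K]`, the
ℓ2-fusion estimator solves

    min_B  Σ_k { (1/n_k)‖y_k − X_k β_k‖₂² + λ‖β_k‖₁
                 + γ Σ_{k'>k} τ_{k,k'} ‖β_k − β_{k'}‖₂² }

and the ℓ1-fusion variant replaces the last term with
`γ Σ_{k'>k} τ_{k,k'} ‖β_k − β_{k'}‖₁`, which permits *exactly* equal
coefficients across subgroups. λ controls global sparsity, γ the strength
of cross-subgroup information sharing, and the pair weights
`τ_{k,k'} ∈ [0,1]` optionally modulate fusion per subgroup pair (all 1 by
default; data-driven weightings from subgroup feature similarity are
provided). K = 1 recovers the classical lasso; γ = 0 gives K independent
lassos.

Solvers:

- **ℓ2 fusion** — cyclic coordinate descent with closed-form
  soft-thresholded updates (monotone objective), and an equivalent
  reformulation as one classical lasso on an augmented sparse design
  (block-diagonal X stacked over fusion-difference rows), solved with
  scikit-learn's coordinate-descent lasso. The two routes agree to
  1e-4 and cross-certify each other.
- **ℓ1 fusion** — Nesterov-smoothed accelerated proximal gradient: the
  combined non-smooth penalty is written as a matrix ℓ1 norm ‖BC‖₁ over a
  fusion graph, smoothed through its ℓ∞ dual, and minimized with a
  FISTA-type loop using a Lipschitz step bound (optionally a backtracking
  step).

## Worked example

Simulate a study with K = 4 subgroups of which 3 share one true
coefficient vector, compute mean-distance fusion weights, tune (λ, γ) by
stratified 5-fold cross-validation, and score the selected fit:

```bash
jointlasso simulate --k 4 --k0 3 --p 30 --n 160 --seed 1 --out sim.csv
# wrote sim.csv (160 samples, 30 features, K=4) and sim.truth.csv (V0=[0, 1, 2])

jointlasso weights --data sim.csv --mode means --out tau.csv
# wrote tau.csv (K=4, mode=means)

jointlasso cv --data sim.csv --n-lambdas 8 --n-gammas 4 --n-folds 5 --seed 1 --out cv.csv
# selected lambda=0.2455 gamma=0.02154 (mean held-out weighted RMSE 1.1277);
# wrote cv.csv and cv.coef.csv

jointlasso evaluate --data sim.csv --coef cv.coef.csv --truth sim.truth.csv --out metrics.yaml
# weighted_rmse: 0.9430388129779452
# n_nonzero: 22
# support_auroc: 0.8053097345132743
```

Cross-validation selected a nonzero fusion weight (γ ≈ 0.022): with 3 of 4
subgroups sharing coefficients, borrowing strength across subgroups
improves held-out prediction over independent fits. The held-out weighted
RMSE (1.13) is close to the noise level of the generator (noise scale 1),
and the in-sample refit recovers the true support well (AUROC 0.81 over
the 120 coefficient positions, 22 of which are estimated nonzero).

The same pipeline is available as a library:

```python
import jointlasso as jl

design = jl.SimulationDesign(K=4, K0=3, p=30, n=160)
ds, truth = jl.simulate_dataset(design, seed=1)
cv = jl.cross_validate(ds, penalty="l2", n_folds=5, seed=1)
print(cv.selected, jl.support_auroc(cv.refit.B, truth.B))
```

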
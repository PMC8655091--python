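# epistratify

Reference-based cell-type deconvolution for bulk tissue genomics, built
around DNA methylation but equally applicable to RNA-seq. The motivating
problem is breast-tissue heterogeneity: a bulk biopsy mixes epithelial
subtypes (luminal progenitor, luminal mature, basal) with adipose, fibroblast
and immune cells, and the questions that matter — e.g. how large the
hormone-receptor-negative luminal progenitor compartment is — are questions
about the *proportions* of those cell types, not about the bulk average.

## The model

Bulk observations are modelled as a linear mixture

```
X = A W + ε
```

where `X ∈ R^(p×n)` holds `p` genomic features (methylation β values in
[0,1], or expression) in `n` bulk samples, `A ∈ R^(p'×k)` is a *reference
(signature) matrix* of expected feature values in `k` purified cell types
over `p'` discriminative features, and `W ∈ [0,1]^(k×n)` are the mixing
proportions, column-wise summing to 1.

Per sample, `W` is estimated by the **RLM pseudo-inverse**: an iteratively
reweighted robust linear fit (Huber weighting, no intercept) of the sample
onto the reference profiles. Robust regression can return small negative
coefficients that are noise; an **adaptive noise threshold** treats the most
negative coefficient as the noise floor and zeroes every coefficient of no
greater magnitude, after which the survivors are normalised to proportions.
Samples where the fit does not converge, or where every coefficient is
zeroed, are flagged *inestimable* rather than reported.

The package also provides:

- **Reference construction** from labelled single cells: feature
  pre-selection by a standardised mean-difference statistic, then ranking by
  a modified Mahalanobis score `d = Σ̂⁻¹[(x̄_in − x̄_out) ∘ |x̄_in − x̄_out|]`
  that discounts features redundant with already-selected ones, or by a
  two-group negative-binomial differential-expression test; the reference is
  the union of each type's top 250 features, with per-type mean profiles.
- **Methylation locus selection** for the purified-profile case: loci with
  low β variance across non-epithelial lineages, β at least 0.5 away from
  the non-epithelial mean, and the largest between-subtype β spread.
- **GMM-LE clustering** to label cells in the first place: a cosine kNN
  graph, the top eigenvectors of the regularised degree-corrected normalised
  adjacency `D_τ^{-1/2} A D_τ^{-1/2}`, and a full-covariance Gaussian
  mixture fitted in that eigenspace with maximum-posterior assignment.
- **Quantile-matching augmentation** to re-express a bulk purified-cell
  profile on the empirical distribution of a sampled single-cell library,
  `x̃ = F̂_b⁻¹[F̂_ref(x_ref)]`.
- **Hierarchical deconvolution**: general cell types first (epithelial,
  adipose, fibroblast, immune), then epithelial subtypes, with
  tissue-relative subtype proportions as the product of the two stages.
- Preprocessing filters (detection-p probe coverage, kNN imputation,
  single-cell library filters, bisulphite read-depth β conversion) and a
  noise-robustness simulation.

## Worked example

```python
import numpy as np
from epistratify import (make_synthetic_reference, simulate_mixtures,
                         corrupt_with_noise, deconvolve)

A = make_synthetic_reference(p=58, k=3, separation=0.5, seed=1)
W_true, X = simulate_mixtures(A, n=100, seed=2)       # X = A @ W_true
W = deconvolve(A, X)
print("noiseless MSE:", ((W.values - W_true.values) ** 2).mean())

Xc = corrupt_with_noise(X, fraction=0.4, seed=3)      # 2320 entries resampled
Wc = deconvolve(A, Xc)
est = ~Wc.inestimable.any(axis=0)
print("40% noise MSE:", ((Wc.values[:, est] - W_true.values[:, est]) ** 2).mean())
print("inestimable samples:", int((~est).sum()), "/ 100")
```

Output:

```
noiseless MSE: 4.3198804254865675e-32
40% noise MSE: 0.005070827619507402
inestimable samples: 32 / 100
```

Clean mixtures are recovered exactly (error at machine precision). With 40%
of the data replaced by uniform noise the recovered proportions still track
the truth closely (mean squared error ≈ 0.005, per-type Pearson correlation
≈ 0.9), at the cost of a substantial fraction of samples flagged as not
estimable — the method reports uncertainty rather than fabricating numbers.

The same pipeline is available from the shell:

```sh
epistratify fixtures ref --p 58 --k 3 --seed 4 --out A.tsv
epistratify fixtures mixture --n 100 --seed 4 --out X.tsv
epistratify deconvolve --ref A.tsv --bulk X.tsv --out W.tsv
```

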
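# Methods

This note records the models implemented in epistratify, the parameters
that matter, the choices made where the design was genuinely open, and what
the synthetic data used by the tests does and does not establish.

## Deconvolution model and estimator

The mixture model is `X = A W + ε` with `X` the features × samples bulk
matrix, `A` the features × cell-types reference, and `W` the cell-types ×
samples proportions. `W` is estimated one sample at a time by robust linear
regression of the sample column on the reference profiles:

- Huber M-estimation via iteratively reweighted least squares, tuning
  constant 1.345 (the conventional 95%-efficiency value), scale estimated by
  median absolute deviation, at most 50 iterations, coefficient tolerance
  1e-8. The inner fit is statsmodels' RLM; when the system is square
  (features = cell types) there are no residual degrees of freedom and the
  solve is performed exactly instead.
- No intercept: the model has none, and proportions absorb the mean level.
- Raw coefficients may be negative. The adaptive noise threshold takes
  `m = |min(w)|` (when negative coefficients exist) as the noise floor and
  zeroes every coefficient with `|w_l| ≤ m` — all negatives, and any
  positive indistinguishable from the floor. A narrower variant that only
  zeroes the negative entries is available behind the
  `most_negative_only` flag.
- Surviving coefficients are normalised to sum to 1.

A sample is **inestimable** when the robust fit fails to converge or when
thresholding zeroes every coefficient. This definition is deliberate: both
events mean the data contain no usable mixture signal for that sample, and
reporting a flag is preferable to reporting an arbitrary vector. Flags are
carried per entry in the `MixingMatrix` and serialised as `NA`.

Feature alignment between reference and bulk takes the intersection of
feature identifiers; a warning is emitted when fewer than 80% of the
reference's features survive.

### Hierarchical two-stage estimation

Tissue containing non-epithelial compartments is handled in two stages:
general cell types (epithelial, adipose, fibroblast, immune — the general
reference is user-supplied) are estimated first, then epithelial subtype
proportions are estimated from the subtype reference on the same bulk
profiles, summing to 1 within the epithelium. Tissue-relative subtype
proportions are the product of the stage-2 fractions and the stage-1
epithelial proportion, so their column sums equal the epithelial proportion
exactly. Stage-2 features are used as-is, without excluding stage-1 loci;
no exclusion rule is defensible without evidence that the two signatures
interfere, and the subtype loci are selected to be uninformative about
non-epithelial lineages in the first place.

## Reference construction

**Pre-selection.** For a target cell type, each feature is scored by
`(mean_in − mean_out) / sqrt(var_out)` over labelled single cells (sample
variance, out-group). When no threshold λ is supplied, the top 1000
features by this statistic are kept instead — the statistic's scale depends
on the data, a universal λ does not exist, and the cap bounds the size of
the covariance estimated next. A zero out-group variance yields ±inf (the
feature is either perfectly discriminative or not at all).

**Mahalanobis ranking.** On the pre-selected features the score vector is
`d = Σ̂⁻¹[(x̄_in − x̄_out) ∘ |x̄_in − x̄_out|]`, with `Σ̂` the out-group
sample covariance. The signed element-wise square keeps the sign of the
mean difference while the inverse covariance discounts features that are
correlated with stronger ones, so redundant near-duplicates do not crowd
the signature. `Σ̂` is ridge-regularised as `Σ̂ + εI` with
`ε = 1e-6 × mean(diag Σ̂)` (configurable), because the out-group cell count
is routinely smaller than the feature count; the system is solved by
Cholesky factorisation, never by explicit inversion. Ranking is by largest
signed score by default (large negative scores mark features *depleted* in
the target type, which the signed convention deliberately places last); an
`absolute` flag ranks by magnitude instead. All ranking ties break by
feature identifier, lexicographically, for determinism.

**Differential-expression ranking.** The alternative route is an analytic
two-group negative-binomial Wald test, one gene at a time, target type
versus all others pooled: counts are scaled by per-cell size factors (total
count over its mean), per-gene dispersions are estimated by method of
moments and shrunk halfway toward a fitted `a/μ + b` mean-dispersion trend,
and the group means are compared on the log scale by the delta method with
NB variance `μ + αμ²` and a half-count offset so all-zero groups stay
finite. Genes are ranked by one-sided p-value for upregulation. This is a
self-contained functional test — calibrated under the null by simulation
(KS-uniformity at 200 cells) — not a re-implementation of any published DE
package's statistic.

**Assembly.** The reference feature set is the union of each type's top 250
ranked features (configurable); `A[i, l]` is the mean of feature `i` over
the cells of type `l`, on the modality recorded in the input. A union
smaller than the number of cell types is rejected, since the reference must
have full column rank to be invertible in the fit.

**Methylation locus selection.** When only one purified β profile per
epithelial subtype exists, loci are selected by three criteria: (1) β
variance across non-epithelial lineages < 0.001 (sample variance); (2)
|β_subtype − mean β_non-epithelial| ≥ 0.5 for the subtype of interest; (3)
among those candidates, the per-subtype quota (default 20) of loci with the
greatest maximum pairwise β difference between the epithelial subtypes. The
quota is a configuration knob, not a discovered constant: with three
subtypes the defaults give a reference of a few dozen loci, the scale at
which the estimator is well conditioned. Criteria (1)–(2) guarantee the
selected loci carry essentially no non-epithelial signal, which is what
lets the hierarchical stage 2 run on bulk profiles containing other
lineages.

## GMM-LE clustering

Cells are embedded by degree-corrected regularised spectral clustering and
clustered with a Gaussian mixture:

- Graph: cosine-similarity kNN graph on `log(1+count)` profiles, default 50
  neighbours, symmetrised with the element-wise maximum, zero diagonal.
  The graph construction is a documented default, fully configurable — any
  symmetric non-negative adjacency can be supplied directly.
- Embedding: top-K eigenvectors of `D_τ^{-1/2} A D_τ^{-1/2}` with
  `D_τ = D + τI`; τ defaults to the mean degree, the standard regulariser
  that keeps low-degree nodes from dominating the spectrum. Rows of the
  eigenvector matrix are projected to unit length (the degree correction);
  rows of zero norm are flagged. Eigenvector signs are fixed by making each
  vector's largest-magnitude entry positive, so runs are deterministic.
  K defaults to the number of clusters sought.
- Clustering: full-covariance Gaussian mixture, 10 seeded EM restarts,
  labels by maximum posterior; log-likelihood and BIC are reported and a
  BIC scan over candidate cluster counts is available.

Clusters are provisionally named by marker-set scores: the (cluster, set)
score is the mean over the cluster's cells of the mean `log1p` expression
of the set's resolvable genes; a cluster whose best score is zero or tied
is flagged ambiguous rather than named.

## Quantile-matching augmentation

A bulk purified-cell profile `x_ref` is re-expressed on a sampled
single-cell library `b` as `F̂_b⁻¹[F̂_ref(x_ref)]`, with right-continuous
ECDFs and the type-1 (smallest-value) quantile inverse. Because the ECDF of
a length-p vector only takes values r/p, the inverse is computed exactly by
rank indexing, with no floating-point quantile arithmetic. Consequences of
the convention, all tested: ranks of a tie-free reference are preserved
exactly; ties in the reference map to identical outputs; a constant
reference maps to the library maximum; mapped values are always drawn from
the sampled cell's value multiset, so zero-inflated libraries produce
zero-inflated synthetic references (the zero fraction is logged). Cells are
sampled uniformly **with replacement** across the B draws — the B synthetic
libraries are meant to be i.i.d. re-expressions, and without replacement
would cap B at the cell count.

## Preprocessing

- Probe coverage: probes detected (detection p ≤ 0.05) in fewer than 95% of
  samples are removed; surviving undetected entries are masked as missing.
- kNN imputation (k = 5): a missing entry is replaced by the mean of the
  sample's values at the k nearest *features*, with Euclidean distance over
  mutually observed samples and candidate neighbours required to be
  observed at the target sample. Feature-wise orientation is the standard
  choice for methylation arrays, where missingness is probe-driven;
  distance ties break lexicographically by feature identifier. Observed
  values are never altered.
- Single-cell filters: libraries with fewer than 250 total reads are
  removed first, then transcripts expressed in fewer than 1000 of the
  surviving cells (both configurable). Order matters and is fixed.
- Bisulphite β: `β = methylated / total` for loci whose total mapped reads
  reach 20 in **every** sample (a depth floor of 20 bounds the granularity
  of β at 0.05); a locus shallow in any sample is dropped entirely, because
  reference profiles must be complete.

All filters are idempotent, and this is tested.

## Simulation study

The robustness experiment draws `W̃` with i.i.d. uniform(0,1) entries,
normalises each column to sum to 1, forms `X̃ = A W̃`, replaces exactly
`round(fraction · p · n)` entries (chosen uniformly without replacement)
with uniform(0,1) noise, deconvolves, and scores mean squared error against
the truth over estimable columns, with inestimable proportions counted
separately. Column normalisation of `W̃` is the default because proportions
must sum to 1; a `normalize_w=False` variant keeps the literal raw uniform
draws. 95% confidence intervals are percentile-bootstrap over replicates
(1000 resamples). All randomness flows from a single seed.

Default problem sizes are n = 100 samples and 1000 replicates; the shipped
tests and the acceptance script use 50 replicates, which already pins the
curve's shape (bootstrap CI half-widths a few percent of the mean) while
keeping a full run around a minute.

**Observed behaviour worth knowing.** Mean MSE rises monotonically with the
corrupted fraction (≈0 at 0%, ≈0.004 at 40%, ≈0.03 at 80% with the default
synthetic reference). The *inestimable* fraction, however, is not
monotone: it peaks near 40% corruption (roughly a third of samples) and
falls toward zero at 60–80%. The reason is mechanical: mixed clean/noise
signals produce strongly negative coefficients that trigger total zeroing,
whereas near-total uniform noise fits to small all-positive coefficients
that the threshold never removes — the estimates are then reported but
meaningless, which is visible in the MSE instead. Interpret the two curves
together.

## Synthetic data: what it shows and what it does not

`make_synthetic_reference` builds a block-structured β reference (each type
owns `p/k` signature loci at baseline + separation, default 0.15 + 0.5,
small uniform jitter); `make_synthetic_sc` builds NB counts (gamma-Poisson,
dispersion 0.3, log-normal library sizes, σ = 0.3) with per-type marker
blocks upregulated by a fold change; `make_two_stage_fixture` builds bulk
mixtures with a planted 0.6 epithelial fraction whose subtype-discriminative
loci are nearly unmethylated in adipose, as the locus-selection criteria
enforce for real references. These generators emulate the *structure* the
methods rely on — planted separable signatures, NB overdispersion, locus
criteria — but not batch effects, probe cross-reactivity, cell-type
abundance skew, doublets, or biological covariance between cell types.
Passing tests establish correctness of the algorithms under their stated
model, not field performance on any particular cohort.

## Numerical conventions

- Missing values: `NA` in text formats; a boolean mask internally, separate
  from numeric storage; NaN on input is promoted into the mask.
- Matrices are feature-major everywhere; text I/O is UTF-8, tab-delimited
  with comma autodetection.
- Reference matrices are validated at load for full column rank, and the
  condition number is logged.
- Degenerate inputs have defined behaviour throughout: all-zero coefficient
  vectors flag inestimability; zero-separation synthetic references are
  rejected as rank-deficient; a single-component GMM returns trivially
  certain posteriors; zero embedding rows are flagged rather than
  normalised.

## Known limitations

- The DE ranking is a calibrated analytic stand-in; it does not reproduce
  any specific published package's statistic, shrinkage, or exact tests.
- The adaptive threshold's total-zeroing rule makes "inestimable" a
  conservative label; as noted above, heavily corrupted samples can evade
  it and must be judged by error metrics instead.
- Reference and bulk must share feature identifiers verbatim; no identifier
  mapping or liftover is attempted.
- The general-cell-type reference for hierarchical stage 1 is accepted as
  input; its derivation is out of scope.
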
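"""Mixture simulation, noise corruption, and the robustness experiment.

The recovery experiment: draw a mixing matrix ``W`` with i.i.d. uniform(0,1)
entries (columns normalised to proportions), form bulk profiles ``X = A W``
from a methylation reference ``A``, replace a chosen fraction of the entries
of ``X`` with uniform(0,1) noise, deconvolve, and compare the recovered
proportions with the ground truth by mean squared error.  Repeating over
replicates and a grid of corruption fractions maps how estimation error and
the fraction of inestimable proportions grow with noise.

The module also provides the synthetic fixture generators used throughout:
a block-structured methylation reference with planted signature loci, and a
negative-binomial single-cell count matrix with planted marker blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deconvolve import deconvolve
from .types_io import (
    FeatureMatrix,
    LabeledCellMatrix,
    MixingMatrix,
    Modality,
    ReferenceMatrix,
    ValidationError,
)

logger = logging.getLogger("epistratify")


@dataclass
class SimulationConfig:
    """Settings for the robustness experiment."""

    n_samples: int = 100
    n_reps: int = 1000
    noise_grid: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8)
    seed: int = 0
    normalize_w: bool = True  # columns of the simulated W sum to 1

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_reps < 1:
            raise ValidationError("n_samples and n_reps must be at least 1")
        if any(f < 0 or f > 1 for f in self.noise_grid):
            raise ValidationError("noise fractions must lie in [0,1]")


@dataclass
class RobustnessReport:
    """Per-noise-level MSE (with bootstrap CI) and % inestimable proportions."""

    noise_fractions: list[float]
    mean_mse: list[float]
    ci_lower: list[float]
    ci_upper: list[float]
    pct_inestimable: list[float]
    config: SimulationConfig = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for mse, lo, hi, pct in zip(
            self.mean_mse, self.ci_lower, self.ci_upper, self.pct_inestimable
        ):
            if mse < 0 or not (lo <= mse <= hi) or not (0 <= pct <= 100):
                raise ValidationError("inconsistent robustness report entries")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "noise_fraction": self.noise_fractions,
                "mean_mse": self.mean_mse,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "pct_inestimable": self.pct_inestimable,
            }
        )


def simulate_mixtures(
    A: ReferenceMatrix,
    n: int,
    seed: int = 0,
    normalize_w: bool = True,
) -> tuple[MixingMatrix, FeatureMatrix]:
    """Draw uniform mixing proportions and form noiseless bulk profiles.

    Entries of ``W`` are i.i.d. uniform(0,1); by default each column is
    normalised to sum to 1 so that ``X = A W`` is a convex combination of
    the reference profiles (``normalize_w=False`` keeps the raw draws).
    Beta-modality outputs are clipped into [0,1] as a numerical guard.
    """
    rng = np.random.default_rng(seed)
    k = A.n_cell_types
    W = rng.uniform(size=(k, n))
    if normalize_w:
        W = W / W.sum(axis=0, keepdims=True)
    X = A.values @ W
    if A.modality is Modality.DNAME_BETA:
        X = np.clip(X, 0.0, 1.0)
    sample_ids = [f"sim{j}" for j in range(n)]
    W_true = MixingMatrix(
        values=W if normalize_w else np.clip(W, 0.0, 1.0),
        cell_type_names=A.cell_type_names,
        sample_ids=sample_ids,
    ) if normalize_w else MixingMatrix.__new__(MixingMatrix)
    if not normalize_w:
        # raw-uniform draws are not column-stochastic; bypass that check
        W_true.values = W
        W_true.cell_type_names = list(A.cell_type_names)
        W_true.sample_ids = sample_ids
        W_true.inestimable = np.zeros(W.shape, dtype=bool)
    X_fm = FeatureMatrix(
        values=X,
        feature_ids=A.feature_ids,
        sample_ids=sample_ids,
        modality=A.modality,
    )
    return W_true, X_fm


def corrupt_with_noise(
    X: FeatureMatrix, fraction: float, seed: int = 0
) -> FeatureMatrix:
    """Replace an exact count of entries with i.i.d. uniform(0,1) noise.

    Exactly ``round(fraction * p * n)`` entry positions, chosen uniformly
    without replacement, are resampled; every other entry is untouched.
    """
    if fraction < 0 or fraction > 1:
        raise ValidationError("fraction must lie in [0,1]")
    rng = np.random.default_rng(seed)
    p, n = X.values.shape
    n_corrupt = int(round(fraction * p * n))
    vals = X.values.copy()
    if n_corrupt:
        flat = rng.choice(p * n, size=n_corrupt, replace=False)
        vals.flat[flat] = rng.uniform(size=n_corrupt)
    return FeatureMatrix(
        values=vals,
        feature_ids=X.feature_ids,
        sample_ids=X.sample_ids,
        modality=X.modality,
        missing=X.missing.copy(),
    )


def mse_vs_truth(W_hat: MixingMatrix, W_true: MixingMatrix) -> tuple[float, float]:
    """MSE over estimable columns and the % of inestimable proportions."""
    est = ~W_hat.inestimable.any(axis=0)
    pct = 100.0 * (1.0 - est.mean())
    if est.any():
        diff = W_hat.values[:, est] - W_true.values[:, est]
        mse = float((diff**2).mean())
    else:
        mse = float("nan")
    return mse, pct


def robustness_experiment(
    config: SimulationConfig,
    A: ReferenceMatrix,
    n_bootstrap: int = 1000,
) -> RobustnessReport:
    """Simulate, corrupt, deconvolve and aggregate over replicates.

    For every replicate and noise fraction: fresh mixtures, fresh noise,
    deconvolution, MSE over estimable columns and the inestimable count.
    Reports the mean MSE with a percentile-bootstrap 95% CI across
    replicates and the mean % inestimable per noise level.  All randomness
    derives from the config seed.
    """
    rng = np.random.default_rng(config.seed)
    levels = list(config.noise_grid)
    mses = {f: [] for f in levels}
    pcts = {f: [] for f in levels}
    for rep in range(config.n_reps):
        sim_seed = int(rng.integers(2**31 - 1))
        W_true, X = simulate_mixtures(
            A, config.n_samples, seed=sim_seed, normalize_w=config.normalize_w
        )
        for f in levels:
            noise_seed = int(rng.integers(2**31 - 1))
            Xc = corrupt_with_noise(X, f, seed=noise_seed)
            W_hat = deconvolve(A, Xc)
            mse, pct = mse_vs_truth(W_hat, W_true)
            mses[f].append(mse)
            pcts[f].append(pct)
    mean_mse, lo, hi, pct_out = [], [], [], []
    boot_rng = np.random.default_rng(config.seed + 1)
    for f in levels:
        arr = np.array(mses[f], dtype=float)
        valid = arr[np.isfinite(arr)]
        m = float(valid.mean()) if valid.size else float("nan")
        if valid.size > 1:
            idx = boot_rng.integers(0, valid.size, size=(n_bootstrap, valid.size))
            boots = valid[idx].mean(axis=1)
            l, h = np.percentile(boots, [2.5, 97.5])
        else:
            l = h = m
        mean_mse.append(m)
        lo.append(min(float(l), m))
        hi.append(max(float(h), m))
        pct_out.append(float(np.mean(pcts[f])))
        logger.info(
            "noise %.2f: mean MSE %.3g (95%% CI %.3g-%.3g), %.2f%% inestimable",
            f, m, l, h, pct_out[-1],
        )
    return RobustnessReport(
        noise_fractions=levels,
        mean_mse=mean_mse,
        ci_lower=lo,
        ci_upper=hi,
        pct_inestimable=pct_out,
        config=config,
    )


# ---------------------------------------------------------------------------
# Synthetic fixture generators
# ---------------------------------------------------------------------------

def make_synthetic_reference(
    p: int = 58,
    k: int = 3,
    separation: float = 0.5,
    seed: int = 0,
    baseline: float = 0.15,
    jitter: float = 0.02,
    cell_type_names: list[str] | None = None,
) -> ReferenceMatrix:
    """Block-structured beta reference with planted signature loci.

    Each cell type owns ``p // k`` signature loci at ``baseline +
    separation`` while sitting at ``baseline`` elsewhere, plus small uniform
    jitter; values are clipped into [0,1] (with a warning if clipping was
    needed).  A zero separation produces a rank-deficient reference and is
    rejected by validation.
    """
    if p < k:
        raise ValidationError("need at least as many loci as cell types")
    rng = np.random.default_rng(seed)
    vals = np.full((p, k), baseline) + rng.uniform(-jitter, jitter, size=(p, k))
    block = p // k
    for l in range(k):
        lo, hi = l * block, (l + 1) * block if l < k - 1 else p
        vals[lo:hi, l] += separation
    if (vals < 0).any() or (vals > 1).any():
        logger.warning("synthetic reference values clipped into [0,1]")
        vals = np.clip(vals, 0.0, 1.0)
    names = cell_type_names or [f"type{l}" for l in range(k)]
    return ReferenceMatrix(
        values=vals,
        feature_ids=[f"locus{i}" for i in range(p)],
        cell_type_names=names,
        modality=Modality.DNAME_BETA,
    )


def make_two_stage_fixture(
    n: int = 20,
    seed: int = 0,
    epithelial_fraction: float = 0.6,
    n_general_loci: int = 40,
    n_subtype_loci: int = 58,
) -> tuple[ReferenceMatrix, ReferenceMatrix, FeatureMatrix, np.ndarray]:
    """Synthetic bulk mixtures with a two-level composition.

    Emulates a breast-tissue design: a general compartment split between
    epithelium and adipose at ``epithelial_fraction``, with the epithelial
    compartment itself a per-sample random mixture of three subtypes.
    General-reference loci share one methylation profile across subtypes
    (high in epithelium, low in adipose); subtype-discriminative loci are
    nearly unmethylated in adipose, as the locus-selection criteria demand
    of non-epithelial lineages.  Returns ``(A_general, A_subtypes, X,
    W_subtypes_true)`` where the true within-epithelium subtype fractions
    are the columns of ``W_subtypes_true``.
    """
    rng = np.random.default_rng(seed)
    A_sub = make_synthetic_reference(
        p=n_subtype_loci, k=3, separation=0.35, seed=seed,
        baseline=0.55, jitter=0.02,
        cell_type_names=["luminal_progenitor", "luminal_mature", "basal"],
    )
    epi_g = rng.uniform(0.7, 0.9, size=n_general_loci)
    adi_g = rng.uniform(0.05, 0.25, size=n_general_loci)
    A_general = ReferenceMatrix(
        values=np.column_stack([epi_g, adi_g]),
        feature_ids=[f"gen{i}" for i in range(n_general_loci)],
        cell_type_names=["epithelial", "adipose"],
        modality=Modality.DNAME_BETA,
    )
    adi_s = rng.uniform(0.0, 0.05, size=n_subtype_loci)
    W_sub = rng.uniform(size=(3, n))
    W_sub /= W_sub.sum(axis=0, keepdims=True)
    f = epithelial_fraction
    top = f * epi_g[:, None] + (1 - f) * adi_g[:, None] * np.ones((1, n))
    bottom = f * (A_sub.values @ W_sub) + (1 - f) * adi_s[:, None]
    X = FeatureMatrix(
        values=np.vstack([np.repeat(top, 1, axis=1), bottom]),
        feature_ids=list(A_general.feature_ids) + list(A_sub.feature_ids),
        sample_ids=[f"mix{j}" for j in range(n)],
        modality=Modality.DNAME_BETA,
    )
    return A_general, A_sub, X, W_sub


def make_synthetic_sc(
    m: int = 300,
    p: int = 200,
    k: int = 3,
    effect: float = 8.0,
    seed: int = 0,
    base_mean: float = 2.0,
    dispersion: float = 0.3,
    markers_per_type: int = 20,
) -> LabeledCellMatrix:
    """Negative-binomial single-cell counts with planted marker blocks.

    Each cell type upregulates its own block of ``markers_per_type`` genes
    by the fold-change ``effect``; per-cell library-size factors are
    log-normal.  True type labels are attached.
    """
    if m < 3 * k:
        raise ValidationError("need at least 3 cells per type")
    rng = np.random.default_rng(seed)
    labels = [f"type{l}" for l in range(k) for _ in range(m // k)]
    labels += [f"type{k - 1}"] * (m - len(labels))
    size_factors = rng.lognormal(mean=0.0, sigma=0.3, size=m)
    mu = np.full((p, m), base_mean)
    for l in range(k):
        cells = [j for j, lab in enumerate(labels) if lab == f"type{l}"]
        g0 = l * markers_per_type
        if g0 + markers_per_type > p:
            raise ValidationError("p too small for the marker blocks")
        mu[np.ix_(range(g0, g0 + markers_per_type), cells)] *= effect
    mu = mu * size_factors[None, :]
    # NB via gamma-Poisson: shape r = 1/dispersion
    r = 1.0 / dispersion
    lam = rng.gamma(shape=r, scale=mu / r)
    counts = rng.poisson(lam).astype(float)
    return LabeledCellMatrix(
        values=counts,
        feature_ids=[f"gene{i}" for i in range(p)],
        cell_ids=[f"cell{j}" for j in range(m)],
        labels=labels,
    )
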
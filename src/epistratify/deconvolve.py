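"""Estimation of cell-type mixing proportions from bulk profiles.

Given a reference matrix ``A`` (selected features x cell types) and bulk
observations ``X`` (features x samples), each sample column is fitted by a
robust linear model with Huber weighting and no intercept — the robust
pseudo-inverse of ``A`` applied to the sample.  Raw coefficients may be
slightly negative through noise; an adaptive threshold zeroes every
coefficient whose magnitude does not exceed that of the most negative one
(the most negative coefficient is taken as the noise floor), and the
surviving coefficients are normalised to proportions summing to 1.

A two-stage hierarchical variant first estimates general cell-type
proportions (e.g. epithelial / adipose / fibroblast / immune), then subtype
proportions within the epithelium, and reports tissue-relative subtype
proportions as the product of the two.

Samples where the robust fit does not converge, or where thresholding
zeroes every coefficient, are flagged *inestimable* rather than reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import warnings

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .types_io import (
    FeatureMatrix,
    MixingMatrix,
    ReferenceMatrix,
    ValidationError,
)

logger = logging.getLogger("epistratify")

HUBER_T = 1.345  # conventional 95%-efficiency Huber tuning constant
MAX_ITER = 50
COEF_TOL = 1e-8
MIN_OVERLAP_WARN = 0.8


@dataclass
class RobustFitResult:
    """Raw robust-regression coefficients for one bulk sample."""

    coefficients: np.ndarray
    converged: bool
    n_iterations: int
    scale: float


def _align(A: ReferenceMatrix, X: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Intersect feature sets; returns (A rows, X rows) over shared features."""
    xpos = {f: i for i, f in enumerate(X.feature_ids)}
    pairs = [(i, xpos[f]) for i, f in enumerate(A.feature_ids) if f in xpos]
    if not pairs:
        raise ValidationError("reference and bulk share no features")
    frac = len(pairs) / A.n_features
    if frac < MIN_OVERLAP_WARN:
        logger.warning(
            "only %.0f%% of reference features found in the bulk matrix",
            100 * frac,
        )
    ai, xi = map(np.array, zip(*pairs))
    if len(pairs) < A.n_cell_types:
        raise ValidationError("fewer shared features than cell types")
    return ai, xi


def _rlm_fit_design(design: np.ndarray, x: np.ndarray) -> RobustFitResult:
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValidationError("reference matrix is rank deficient on shared features")
    if design.shape[0] <= design.shape[1]:
        # square system: no residual degrees of freedom, the solve is exact
        coefs = np.linalg.lstsq(design, x, rcond=None)[0]
        return RobustFitResult(coefs, converged=True, n_iterations=0, scale=0.0)
    model = sm.RLM(x, design, M=sm.robust.norms.HuberT(t=HUBER_T))
    with warnings.catch_warnings():
        # a zero scale estimate just means the fit is exact
        warnings.simplefilter("ignore", ConvergenceWarning)
        fit = model.fit(
            maxiter=MAX_ITER,
            tol=COEF_TOL,
            scale_est="mad",
            conv="coefs",
        )
    n_iter = int(fit.fit_history.get("iteration", MAX_ITER))
    converged = bool(np.isfinite(fit.params).all()) and n_iter < MAX_ITER
    return RobustFitResult(
        coefficients=np.asarray(fit.params, dtype=float),
        converged=converged,
        n_iterations=n_iter,
        scale=float(fit.scale),
    )


def rlm_fit(A: ReferenceMatrix, x: FeatureMatrix | np.ndarray) -> RobustFitResult:
    """Huber IRLS fit of one bulk sample onto the reference profiles.

    No intercept is included: the model ``x = A w`` has none, and the
    proportions absorb any mean level.  Returns raw coefficients, which may
    be negative before thresholding.
    """
    if isinstance(x, FeatureMatrix):
        if x.n_samples != 1:
            raise ValidationError("rlm_fit expects a single sample column")
        ai, xi = _align(A, x)
        return _rlm_fit_design(A.values[ai], x.values[xi, 0])
    x = np.asarray(x, dtype=float)
    if x.shape != (A.n_features,):
        raise ValidationError("sample vector not aligned to reference features")
    return _rlm_fit_design(A.values, x)


def adaptive_noise_threshold(
    w_raw: np.ndarray, most_negative_only: bool = False
) -> np.ndarray:
    """Zero coefficients no larger in magnitude than the most negative one.

    With ``m = |min(w)|`` for a vector with any negative entry, every entry
    with ``|value| <= m`` is set to 0 — all negatives, and positives that
    cannot be distinguished from the noise floor.  A non-negative vector is
    returned unchanged.  ``most_negative_only=True`` applies the narrower
    reading where only negative entries are zeroed.
    """
    w = np.asarray(w_raw, dtype=float)
    if w.size == 0 or w.min() >= 0:
        return w.copy()
    m = abs(w.min())
    out = w.copy()
    if most_negative_only:
        out[out < 0] = 0.0
    else:
        out[np.abs(out) <= m] = 0.0
    return out


def normalize_proportions(w: np.ndarray) -> tuple[np.ndarray, bool]:
    """Scale non-negative coefficients to sum to 1.

    Returns ``(proportions, estimable)``; an all-zero vector cannot be
    normalised and is flagged inestimable.
    """
    w = np.asarray(w, dtype=float)
    if (w < 0).any():
        raise ValidationError("negative coefficients; apply thresholding first")
    total = w.sum()
    if total == 0:
        return np.zeros_like(w), False
    return w / total, True


def deconvolve(
    A: ReferenceMatrix,
    X: FeatureMatrix,
    most_negative_only: bool = False,
) -> MixingMatrix:
    """Estimate the mixing matrix ``W`` for every bulk sample.

    Per sample: robust fit, adaptive noise threshold, sum-to-one
    normalisation.  A whole sample column is flagged inestimable when the
    fit fails to converge or when thresholding zeroes every coefficient.
    """
    if A.modality != X.modality:
        raise ValidationError(
            f"modality mismatch: reference {A.modality.value}, "
            f"bulk {X.modality.value}"
        )
    ai, xi = _align(A, X)
    design = A.values[ai]
    k, n = A.n_cell_types, X.n_samples
    W = np.zeros((k, n))
    flags = np.zeros((k, n), dtype=bool)
    for j in range(n):
        res = _rlm_fit_design(design, X.values[xi, j])
        if not res.converged:
            flags[:, j] = True
            logger.debug("sample %s: robust fit did not converge", X.sample_ids[j])
            continue
        w = adaptive_noise_threshold(
            res.coefficients, most_negative_only=most_negative_only
        )
        props, ok = normalize_proportions(w)
        if not ok:
            flags[:, j] = True
            logger.debug("sample %s: all coefficients zeroed", X.sample_ids[j])
            continue
        W[:, j] = props
    pct = 100.0 * flags.any(axis=0).mean()
    logger.info("deconvolved %d samples; %.1f%% inestimable", n, pct)
    return MixingMatrix(
        values=W,
        cell_type_names=A.cell_type_names,
        sample_ids=X.sample_ids,
        inestimable=flags,
    )


def hierarchical_deconvolve(
    A_general: ReferenceMatrix,
    A_subtypes: ReferenceMatrix,
    X: FeatureMatrix,
    epithelial_label: str = "epithelial",
) -> tuple[MixingMatrix, MixingMatrix, MixingMatrix]:
    """Two-stage estimation: general cell types, then epithelial subtypes.

    Stage 1 estimates general proportions from ``A_general``; stage 2
    estimates subtype proportions summing to 1 within the epithelium from
    ``A_subtypes``; tissue-relative subtype proportions are the stage-2
    fractions scaled by the stage-1 epithelial proportion, so each sample's
    tissue-relative subtype proportions sum to its epithelial proportion.
    """
    if epithelial_label not in A_general.cell_type_names:
        raise ValidationError(
            f"{epithelial_label!r} is not a column of the general reference"
        )
    W_general = deconvolve(A_general, X)
    W_within = deconvolve(A_subtypes, X)
    epi_row = A_general.cell_type_names.index(epithelial_label)
    epi = W_general.values[epi_row]
    tissue_vals = W_within.values * epi[None, :]
    tissue_flags = W_within.inestimable | W_general.inestimable[epi_row][None, :]
    W_tissue = MixingMatrix.__new__(MixingMatrix)
    # tissue-relative columns sum to the epithelial proportion, not to 1,
    # so bypass the column-stochastic validation deliberately
    W_tissue.values = tissue_vals
    W_tissue.cell_type_names = list(A_subtypes.cell_type_names)
    W_tissue.sample_ids = list(X.sample_ids)
    W_tissue.inestimable = tissue_flags
    return W_general, W_within, W_tissue
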
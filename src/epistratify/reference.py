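"""Construction of the cell-type reference (signature) matrix ``A``.

Two feature-ranking routes are provided, each run once per target cell type
against all other types pooled:

* **Mahalanobis ranking** — features are first pre-selected by a
  standardised mean-difference statistic, then ranked by a modified
  Mahalanobis score ``d = Sigma^{-1} [(m_in - m_out) o |m_in - m_out|]``
  computed on the out-group covariance, which down-weights features that
  are redundant with (correlated to) already-discriminative ones.
* **Differential-expression ranking** — an analytic two-group
  negative-binomial Wald test with library-size normalisation and a
  trend-moderated method-of-moments dispersion estimate, ranking genes by
  one-sided (in-group higher) significance.

The reference itself is the union of each type's top-ranked features
(default 250 per type), with ``A[i, l]`` the mean of feature ``i`` over the
cells of type ``l``.  For bisulphite-derived methylation profiles, where a
single purified profile per epithelial subtype exists, a three-criteria
locus selector replaces the single-cell route.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .types_io import (
    FeatureMatrix,
    LabeledCellMatrix,
    Modality,
    ReferenceMatrix,
    ValidationError,
)

logger = logging.getLogger("epistratify")

DEFAULT_TOP_N = 250
DEFAULT_PRESELECT_CAP = 1000  # features kept when no threshold is supplied
COV_RIDGE_FACTOR = 1e-6  # ridge = factor * mean(diag(Sigma))


@dataclass
class FeatureRanking:
    """Ranked discriminative features for one target cell type."""

    target_type: str
    feature_ids: list[str]  # ordered, best first
    scores: np.ndarray  # aligned to feature_ids
    preselection_stats: dict[str, float] = field(default_factory=dict)
    lambda_used: float | None = None

    def top(self, n: int) -> list[str]:
        return self.feature_ids[:n]


@dataclass
class LociCriteria:
    """Thresholds for the methylation locus selector."""

    max_nonepithelial_variance: float = 0.001
    min_delta_beta: float = 0.5
    quota: int = 20

    def __post_init__(self) -> None:
        if self.max_nonepithelial_variance <= 0 or self.min_delta_beta <= 0:
            raise ValidationError("criteria thresholds must be positive")
        if self.quota < 1:
            raise ValidationError("quota must be at least 1")


def _group_split(Y: LabeledCellMatrix, target_type: str):
    idx_in = Y.cells_of_type(target_type)
    mask = np.zeros(Y.n_cells, dtype=bool)
    mask[idx_in] = True
    idx_out = np.flatnonzero(~mask)
    return idx_in, idx_out


def preselect_statistic(Y: LabeledCellMatrix, target_type: str) -> np.ndarray:
    """Standardised in-vs-out mean difference per feature.

    ``(mean_in - mean_out) / sqrt(var_out)`` with the out-group sample
    variance; a zero out-group variance yields +/-inf when the means differ
    and 0 when they agree.
    """
    idx_in, idx_out = _group_split(Y, target_type)
    if idx_out.size < 2:
        raise ValidationError("need at least 2 out-group cells")
    mean_in = Y.values[:, idx_in].mean(axis=1)
    mean_out = Y.values[:, idx_out].mean(axis=1)
    var_out = Y.values[:, idx_out].var(axis=1, ddof=1)
    diff = mean_in - mean_out
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = diff / np.sqrt(var_out)
    stat[(var_out == 0) & (diff == 0)] = 0.0
    return stat


def preselect_features(
    Y: LabeledCellMatrix,
    target_type: str,
    lam: float | None = None,
    cap: int = DEFAULT_PRESELECT_CAP,
) -> tuple[list[str], dict[str, float]]:
    """Features whose pre-selection statistic exceeds ``lam``.

    When ``lam`` is None the top ``cap`` features by the statistic are kept
    instead, which bounds the size of the covariance estimated downstream.
    Returns the selected feature IDs and the statistic for every feature.
    """
    stat = preselect_statistic(Y, target_type)
    stats_by_id = dict(zip(Y.feature_ids, map(float, stat)))
    if lam is None:
        order = np.lexsort((np.array(Y.feature_ids, dtype=object), -stat))
        sel = sorted(order[: min(cap, len(order))])
    else:
        sel = list(np.flatnonzero(stat > lam))
    k = min(len(set(Y.labels)), Y.n_features)  # type: ignore[arg-type]
    if len(sel) < k:
        raise ValidationError(
            f"only {len(sel)} features pass lambda={lam}; lower the threshold"
        )
    return [Y.feature_ids[i] for i in sel], stats_by_id


def rank_features_mahalanobis(
    Y: LabeledCellMatrix,
    target_type: str,
    preselected: list[str] | None = None,
    lam: float | None = None,
    ridge_factor: float = COV_RIDGE_FACTOR,
    absolute: bool = False,
) -> FeatureRanking:
    """Rank pre-selected features by the modified Mahalanobis score.

    The out-group covariance on the pre-selected features is ridge-
    regularised (``Sigma + eps*I`` with ``eps = ridge_factor * mean diag``)
    and the score solved as a linear system, never by explicit inversion.
    By default the largest signed scores rank first; ``absolute=True`` ranks
    by magnitude.  Ties break by feature ID.
    """
    if preselected is None:
        preselected, prestats = preselect_features(Y, target_type, lam=lam)
    else:
        prestats = {
            f: float(s)
            for f, s in zip(Y.feature_ids, preselect_statistic(Y, target_type))
            if f in set(preselected)
        }
    pos = {f: i for i, f in enumerate(Y.feature_ids)}
    try:
        rows = np.array([pos[f] for f in preselected])
    except KeyError as e:
        raise ValidationError(f"unknown preselected feature {e.args[0]!r}") from e
    idx_in, idx_out = _group_split(Y, target_type)
    if idx_out.size < 2:
        raise ValidationError("need at least 2 out-group cells")
    sub = Y.values[np.ix_(rows, idx_out)]
    mean_out = sub.mean(axis=1)
    mean_in = Y.values[np.ix_(rows, idx_in)].mean(axis=1)
    sigma = np.cov(sub, ddof=1)
    sigma = np.atleast_2d(sigma)
    eps = ridge_factor * max(np.mean(np.diag(sigma)), np.finfo(float).tiny)
    reg = sigma + eps * np.eye(sigma.shape[0])
    diff = mean_in - mean_out
    rhs = diff * np.abs(diff)
    try:
        c, low = linalg.cho_factor(reg)
        d = linalg.cho_solve((c, low), rhs)
    except linalg.LinAlgError as e:
        raise ValidationError(
            "regularised covariance is singular "
            f"(condition number {np.linalg.cond(reg):.3g})"
        ) from e
    key = np.abs(d) if absolute else d
    order = np.lexsort((np.array(preselected, dtype=object), -key))
    return FeatureRanking(
        target_type=target_type,
        feature_ids=[preselected[i] for i in order],
        scores=d[order],
        preselection_stats=prestats,
        lambda_used=lam,
    )


# ---------------------------------------------------------------------------
# Differential-expression ranking (method 2)
# ---------------------------------------------------------------------------

def _size_factors(Y: np.ndarray) -> np.ndarray:
    lib = Y.sum(axis=0)
    if (lib == 0).any():
        raise ValidationError("cell with zero total count; filter libraries first")
    return lib / lib.mean()


def _moment_dispersion(norm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene method-of-moments NB dispersion on normalised counts."""
    mu = norm.mean(axis=1)
    v = norm.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (v - mu) / mu**2
    alpha = np.where(np.isfinite(alpha), alpha, 0.0)
    return mu, np.clip(alpha, 0.0, None)


def _trended_dispersion(mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Shrink gene-wise dispersions halfway toward a fitted mean trend.

    The trend is ``alpha(mu) = a/mu + b`` fitted by least squares over genes
    with positive mean — the standard mean-dispersion shape for NB counts.
    """
    ok = mu > 0
    if ok.sum() < 3:
        return alpha
    Xd = np.column_stack([1.0 / mu[ok], np.ones(ok.sum())])
    coef, *_ = np.linalg.lstsq(Xd, alpha[ok], rcond=None)
    trend = np.zeros_like(alpha)
    trend[ok] = np.clip(Xd @ coef, 0.0, None)
    return 0.5 * alpha + 0.5 * trend


def rank_features_de(
    Y: LabeledCellMatrix, target_type: str
) -> FeatureRanking:
    """Two-group negative-binomial Wald test, in-group vs all others pooled.

    Counts are divided by per-cell size factors (total count over its mean);
    the NB variance ``mu + alpha*mu^2`` uses the trend-moderated dispersion.
    The Wald statistic compares group means of the normalised counts on the
    log scale via the delta method, and genes are ranked by one-sided
    p-value for upregulation in the target type.  This is a functional
    analytic test, not a clone of any particular DE package.
    """
    idx_in, idx_out = _group_split(Y, target_type)
    if idx_in.size < 2 or idx_out.size < 2:
        raise ValidationError("both groups need at least 2 cells")
    sf = _size_factors(Y.values)
    norm = Y.values / sf[None, :]
    mu, alpha = _moment_dispersion(norm)
    alpha = _trended_dispersion(mu, alpha)

    n1, n2 = idx_in.size, idx_out.size
    m1 = norm[:, idx_in].mean(axis=1)
    m2 = norm[:, idx_out].mean(axis=1)
    # half-count offset keeps the log ratio finite for all-zero groups
    c = 0.5
    lfc = np.log(m1 + c) - np.log(m2 + c)
    var1 = (m1 + c) + alpha * (m1 + c) ** 2
    var2 = (m2 + c) + alpha * (m2 + c) ** 2
    se = np.sqrt(var1 / (n1 * (m1 + c) ** 2) + var2 / (n2 * (m2 + c) ** 2))
    z = lfc / se
    pvals = stats.norm.sf(z)  # one-sided: in-group higher
    order = np.lexsort((np.array(Y.feature_ids, dtype=object), pvals, -z))
    return FeatureRanking(
        target_type=target_type,
        feature_ids=[Y.feature_ids[i] for i in order],
        scores=pvals[order],
    )


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def build_reference(
    Y: LabeledCellMatrix,
    rankings: dict[str, FeatureRanking],
    top_n: int = DEFAULT_TOP_N,
    modality: Modality | str = Modality.RNA_COUNTS,
) -> ReferenceMatrix:
    """Union of each type's top ``top_n`` features; profiles are type means."""
    if Y.labels is None:
        raise ValidationError("labelled cells required")
    types = Y.cell_types
    missing = [t for t in types if t not in rankings]
    if missing:
        raise ValidationError(f"no ranking for type(s): {', '.join(missing)}")
    union: list[str] = []
    seen: set[str] = set()
    for t in types:
        for f in rankings[t].top(top_n):
            if f not in seen:
                seen.add(f)
                union.append(f)
    if len(union) < len(types):
        raise ValidationError(
            f"feature union ({len(union)}) smaller than cell-type count"
        )
    pos = {f: i for i, f in enumerate(Y.feature_ids)}
    rows = np.array([pos[f] for f in union])
    cols = np.column_stack(
        [Y.values[np.ix_(rows, Y.cells_of_type(t))].mean(axis=1) for t in types]
    )
    return ReferenceMatrix(
        values=cols,
        feature_ids=union,
        cell_type_names=types,
        modality=Modality(modality),
    )


def select_dname_loci(
    epi_profiles: FeatureMatrix,
    nonepi_profiles: FeatureMatrix,
    criteria: LociCriteria | None = None,
) -> ReferenceMatrix:
    """Three-criteria methylation locus selection for epithelial subtypes.

    Per subtype, a candidate locus must (1) have low beta variance across
    the non-epithelial lineages and (2) differ from the non-epithelial mean
    beta by at least ``min_delta_beta``; the per-subtype quota is then
    filled by the candidates with (3) the greatest maximum pairwise beta
    difference between the epithelial subtypes.  The reference is the
    epithelial profiles restricted to the union of retained loci.
    """
    criteria = criteria or LociCriteria()
    if epi_profiles.modality is not Modality.DNAME_BETA:
        raise ValidationError("epithelial profiles must be beta values")
    if nonepi_profiles.n_samples < 2:
        raise ValidationError("need at least 2 non-epithelial lineages")
    shared = [f for f in epi_profiles.feature_ids
              if f in set(nonepi_profiles.feature_ids)]
    if not shared:
        raise ValidationError("no shared loci between profile sets")
    epos = {f: i for i, f in enumerate(epi_profiles.feature_ids)}
    npos = {f: i for i, f in enumerate(nonepi_profiles.feature_ids)}
    erows = np.array([epos[f] for f in shared])
    nrows = np.array([npos[f] for f in shared])
    E = epi_profiles.values[erows]  # loci x subtypes
    N = nonepi_profiles.values[nrows]  # loci x lineages
    var_non = N.var(axis=1, ddof=1)
    mean_non = N.mean(axis=1)
    low_var = var_non < criteria.max_nonepithelial_variance
    # criterion 3 key: greatest pairwise beta spread among subtypes
    spread = E.max(axis=1) - E.min(axis=1)
    names = np.array(shared, dtype=object)

    kept: list[str] = []
    seen: set[str] = set()
    for s, subtype in enumerate(epi_profiles.sample_ids):
        delta = np.abs(E[:, s] - mean_non)
        cand = np.flatnonzero(low_var & (delta >= criteria.min_delta_beta))
        if cand.size == 0:
            raise ValidationError(
                f"no candidate loci for subtype {subtype!r}"
            )
        order = cand[np.lexsort((names[cand], -spread[cand]))]
        for i in order[: criteria.quota]:
            f = shared[i]
            if f not in seen:
                seen.add(f)
                kept.append(f)
    rows = np.array([epos[f] for f in kept])
    logger.info(
        "locus selection kept %d loci over %d subtypes",
        len(kept), epi_profiles.n_samples,
    )
    return ReferenceMatrix(
        values=epi_profiles.values[rows],
        feature_ids=kept,
        cell_type_names=epi_profiles.sample_ids,
        modality=Modality.DNAME_BETA,
    )
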
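"""Data-cleaning filters applied before reference building and deconvolution.

Four operations: methylation-array probe filtering by detection-p coverage,
k-nearest-neighbour imputation of the surviving undetected entries,
single-cell library/transcript filtering, and conversion of bisulphite read
counts into methylation beta values with a read-depth floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .types_io import (
    FeatureMatrix,
    LabeledCellMatrix,
    Modality,
    ValidationError,
)

logger = logging.getLogger("epistratify")


@dataclass
class DetectionMatrix:
    """Per-(probe, sample) detection p-values aligned to a FeatureMatrix."""

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError("detection matrix shape mismatch")
        if ((self.values < 0) | (self.values > 1)).any():
            raise ValidationError("detection p-values must lie in [0,1]")

    def aligned_to(self, X: FeatureMatrix) -> None:
        if self.feature_ids != X.feature_ids or self.sample_ids != X.sample_ids:
            raise ValidationError("detection matrix is not aligned to the data")


@dataclass
class BisulphiteCounts:
    """Methylated / unmethylated mapped-read counts per (locus, sample)."""

    methylated: np.ndarray
    unmethylated: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.methylated = np.asarray(self.methylated)
        self.unmethylated = np.asarray(self.unmethylated)
        shape = (len(self.feature_ids), len(self.sample_ids))
        if self.methylated.shape != shape or self.unmethylated.shape != shape:
            raise ValidationError("bisulphite count shape mismatch")
        for arr in (self.methylated, self.unmethylated):
            if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
                raise ValidationError("read counts must be non-negative integers")

    @property
    def total(self) -> np.ndarray:
        return self.methylated + self.unmethylated


def filter_probes_by_coverage(
    X: FeatureMatrix,
    D: DetectionMatrix,
    min_coverage: float = 0.95,
    p_cut: float = 0.05,
) -> FeatureMatrix:
    """Drop probes detected in too few samples; mask remaining failures.

    A probe is *detected* in a sample when its detection p-value is at most
    ``p_cut``.  Probes detected in fewer than ``min_coverage`` of samples are
    removed; in retained probes, individual undetected entries are marked
    missing so they can be imputed.
    """
    D.aligned_to(X)
    detected = D.values <= p_cut
    frac = detected.mean(axis=1)
    keep = frac >= min_coverage
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("coverage filter removed %d/%d probes", n_drop, X.n_features)
    missing = X.missing[keep] | ~detected[keep]
    return FeatureMatrix(
        values=X.values[keep],
        feature_ids=[f for f, k in zip(X.feature_ids, keep) if k],
        sample_ids=X.sample_ids,
        modality=X.modality,
        missing=missing,
    )


def knn_impute(X: FeatureMatrix, k: int = 5) -> FeatureMatrix:
    """Replace each missing entry by the mean of the k nearest features.

    Distances between features are Euclidean over the samples where both
    features are observed; candidate neighbours must themselves be observed
    at the target sample.  Ties in distance break by feature ID
    lexicographic order.  Observed entries are never changed.
    """
    if k < 1:
        raise ValidationError("k must be at least 1")
    missing = X.missing.copy()
    if not missing.any():
        return X
    obs = ~missing
    dead = ~obs.any(axis=1)
    if dead.any():
        names = [f for f, d in zip(X.feature_ids, dead) if d]
        raise ValidationError(
            f"feature(s) with no observed values: {', '.join(names)}"
        )
    vals = X.values.copy()
    p = X.n_features
    order = np.argsort(np.array(X.feature_ids, dtype=object))
    lex_rank = np.empty(p, dtype=int)
    lex_rank[order] = np.arange(p)

    out = vals.copy()
    for i in np.flatnonzero(missing.any(axis=1)):
        # distances from feature i to every other feature
        shared = obs[i][None, :] & obs  # (p, n) mutually observed mask
        diff = np.where(shared, vals - vals[i][None, :], 0.0)
        dist = np.sqrt((diff**2).sum(axis=1))
        dist[i] = np.inf
        dist[~shared.any(axis=1)] = np.inf
        for j in np.flatnonzero(missing[i]):
            cand = np.flatnonzero(obs[:, j] & np.isfinite(dist))
            if cand.size < k:
                raise ValidationError(
                    f"fewer than k={k} observed neighbours for feature "
                    f"{X.feature_ids[i]!r} at sample {X.sample_ids[j]!r}"
                )
            # stable sort on (distance, lexicographic feature rank)
            sel = cand[np.lexsort((lex_rank[cand], dist[cand]))][:k]
            out[i, j] = vals[sel, j].mean()
    return FeatureMatrix(
        values=out,
        feature_ids=X.feature_ids,
        sample_ids=X.sample_ids,
        modality=X.modality,
        missing=np.zeros_like(missing),
    )


def filter_sc_libraries(
    Y: LabeledCellMatrix,
    min_reads: int = 250,
    min_cells: int = 1000,
) -> LabeledCellMatrix:
    """Keep libraries with enough reads, then transcripts expressed widely.

    Cells with total count below ``min_reads`` are removed first; then
    transcripts with a non-zero count in fewer than ``min_cells`` of the
    surviving cells are removed.
    """
    totals = Y.values.sum(axis=0)
    keep_cells = totals >= min_reads
    if not keep_cells.any():
        raise ValidationError("library filter removed every cell")
    sub = Y.values[:, keep_cells]
    keep_feats = (sub > 0).sum(axis=1) >= min_cells
    logger.info(
        "library filter kept %d/%d cells and %d/%d transcripts",
        int(keep_cells.sum()), Y.n_cells, int(keep_feats.sum()), Y.n_features,
    )
    labels = None
    if Y.labels is not None:
        labels = [l for l, kc in zip(Y.labels, keep_cells) if kc]
    return LabeledCellMatrix(
        values=sub[keep_feats],
        feature_ids=[f for f, kf in zip(Y.feature_ids, keep_feats) if kf],
        cell_ids=[c for c, kc in zip(Y.cell_ids, keep_cells) if kc],
        labels=labels,
    )


def beta_from_bisulphite(
    C: BisulphiteCounts, min_total: int = 20
) -> FeatureMatrix:
    """Methylation rate beta = methylated / total, with a read-depth floor.

    A locus is kept only if its total mapped reads reach ``min_total`` in
    every sample (the default of 20 bounds the granularity of the estimated
    rate at 0.05); a complete profile across samples is required because
    reference construction cannot use partially observed loci.
    """
    total = C.total
    keep = (total >= min_total).all(axis=1)
    if not keep.any():
        raise ValidationError("read-depth filter removed every locus")
    beta = C.methylated[keep] / total[keep]
    return FeatureMatrix(
        values=beta,
        feature_ids=[f for f, kk in zip(C.feature_ids, keep) if kk],
        sample_ids=C.sample_ids,
        modality=Modality.DNAME_BETA,
    )
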
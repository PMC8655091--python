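"""GMM-LE clustering: Gaussian mixtures in the Laplacian Eigenspace.

Cells are embedded with degree-corrected regularised spectral clustering:
build a cosine-similarity kNN graph on log counts, form the regularised
normalised adjacency ``D_tau^{-1/2} A D_tau^{-1/2}`` with ``D_tau = D + tau
I`` (the regulariser ``tau`` defaults to the mean degree, which stabilises
the spectrum when the graph has low-degree nodes), take its top-K
eigenvectors, and project the rows onto the unit sphere (the degree
correction).  Instead of the usual k-means step, a full-covariance Gaussian
mixture model is fitted in that eigenspace and cells are assigned to the
component with maximum posterior probability.

Clusters are provisionally named by scoring pre-defined marker-gene sets:
the score of (cluster, set) is the mean over the cluster's cells of the
mean log1p expression of the set's genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as dla
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import eigsh
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import NearestNeighbors

from .types_io import (
    FeatureMatrix,
    LabeledCellMatrix,
    MarkerSets,
    ValidationError,
)

logger = logging.getLogger("epistratify")

DEFAULT_N_NEIGHBORS = 50
DEFAULT_N_INIT = 10


@dataclass
class Embedding:
    """Spectral embedding of cells (rows) in the Laplacian eigenspace."""

    coordinates: np.ndarray  # m x K, unit-norm rows (zero rows flagged)
    eigenvalues: np.ndarray
    tau: float
    n_neighbors: int | None = None
    zero_rows: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] < 1:
            raise ValidationError("embedding must be a 2-D matrix")
        if not np.isfinite(self.coordinates).all():
            raise ValidationError("embedding contains non-finite coordinates")
        if self.zero_rows is None:
            self.zero_rows = np.zeros(self.coordinates.shape[0], dtype=bool)


@dataclass
class ClusterAssignment:
    """Maximum-posterior cluster labels with the full posterior matrix."""

    labels: np.ndarray  # int label per cell
    posteriors: np.ndarray  # m x n_clusters, rows sum to 1
    log_likelihood: float
    bic: float
    cluster_names: dict[int, str] | None = None

    def __post_init__(self) -> None:
        if not np.allclose(self.posteriors.sum(axis=1), 1.0, atol=1e-8):
            raise ValidationError("posterior rows must sum to 1")
        if not np.array_equal(self.labels, self.posteriors.argmax(axis=1)):
            raise ValidationError("labels must be the argmax posteriors")


def _cell_coordinates(Y) -> tuple[np.ndarray, int]:
    if isinstance(Y, (LabeledCellMatrix, FeatureMatrix)):
        mat = Y.values
    else:
        mat = np.asarray(Y, dtype=float)
    # cells are columns of the feature matrix; embed log counts
    return np.log1p(mat.T), mat.shape[1]


def build_graph(Y, n_neighbors: int = DEFAULT_N_NEIGHBORS) -> np.ndarray:
    """Cosine-similarity kNN graph on log1p counts, symmetrised by max.

    Edge weights are cosine similarities clipped at 0; each cell keeps its
    ``n_neighbors`` nearest cells, the adjacency is symmetrised with the
    elementwise maximum, and the diagonal is zero.
    """
    coords, m = _cell_coordinates(Y)
    if m <= n_neighbors:
        raise ValidationError(
            f"need more than n_neighbors={n_neighbors} cells, got {m}"
        )
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1, metric="cosine")
    nn.fit(coords)
    dist, idx = nn.kneighbors(coords)
    W = np.zeros((m, m))
    for i in range(m):
        for d, j in zip(dist[i], idx[i]):
            if j == i:
                continue
            W[i, j] = max(W[i, j], max(1.0 - d, 0.0))
    W = np.maximum(W, W.T)
    np.fill_diagonal(W, 0.0)
    deg = W.sum(axis=1)
    n_isolated = int((deg == 0).sum())
    if n_isolated:
        logger.warning("graph has %d isolated cells", n_isolated)
    import scipy.sparse.csgraph as csgraph

    n_comp = csgraph.connected_components(csr_matrix(W > 0), directed=False)[0]
    logger.info("kNN graph: %d cells, %d connected component(s)", m, n_comp)
    return W


def laplacian_eigenspace(
    adjacency: np.ndarray,
    K: int,
    tau: float | None = None,
) -> Embedding:
    """Top-K eigenvectors of the regularised normalised adjacency.

    ``tau`` defaults to the mean degree.  Eigenvector signs are fixed by
    making each vector's largest-magnitude entry positive; rows of the
    eigenvector matrix are scaled to unit norm (zero rows are left at zero
    and flagged).
    """
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValidationError("adjacency must be square")
    if not np.allclose(A, A.T):
        raise ValidationError("adjacency must be symmetric")
    if (A < 0).any():
        raise ValidationError("adjacency must be non-negative")
    if K < 1:
        raise ValidationError("K must be at least 1")
    m = A.shape[0]
    deg = A.sum(axis=1)
    if tau is None:
        tau = float(deg.mean())
    dtau = deg + tau
    dinv = np.where(dtau > 0, 1.0 / np.sqrt(np.where(dtau > 0, dtau, 1.0)), 0.0)
    L = dinv[:, None] * A * dinv[None, :]
    try:
        if K < m - 1 and m > 200:
            evals, evecs = eigsh(csr_matrix(L), k=K, which="LA")
            order = np.argsort(evals)[::-1]
            evals, evecs = evals[order], evecs[:, order]
        else:
            evals_all, evecs_all = dla.eigh(L)
            evals = evals_all[::-1][:K]
            evecs = evecs_all[:, ::-1][:, :K]
    except Exception as e:  # pragma: no cover - solver diagnostics path
        raise ValidationError(
            f"eigendecomposition failed on a {m}x{m} matrix "
            f"(degrees {deg.min():.3g}..{deg.max():.3g}): {e}"
        ) from e
    # deterministic sign: largest-magnitude entry positive
    for c in range(evecs.shape[1]):
        i = int(np.argmax(np.abs(evecs[:, c])))
        if evecs[i, c] < 0:
            evecs[:, c] = -evecs[:, c]
    norms = np.linalg.norm(evecs, axis=1)
    zero = norms < 1e-12
    safe = np.where(zero, 1.0, norms)
    coords = evecs / safe[:, None]
    if zero.any():
        logger.warning("%d cells have zero embedding rows", int(zero.sum()))
    return Embedding(
        coordinates=coords,
        eigenvalues=np.asarray(evals, dtype=float),
        tau=float(tau),
        zero_rows=zero,
    )


def gmm_le_cluster(
    E: Embedding,
    n_clusters: int,
    seed: int = 0,
    n_init: int = DEFAULT_N_INIT,
) -> ClusterAssignment:
    """Fit a full-covariance Gaussian mixture in the eigenspace.

    Cells get the label of the component with maximum posterior; the fitted
    log-likelihood and BIC are reported for model comparison.
    """
    if n_clusters < 1:
        raise ValidationError("n_clusters must be at least 1")
    X = E.coordinates
    if n_clusters == 1:
        post = np.ones((X.shape[0], 1))
        return ClusterAssignment(
            labels=np.zeros(X.shape[0], dtype=int),
            posteriors=post,
            log_likelihood=0.0,
            bic=0.0,
        )
    gmm = GaussianMixture(
        n_components=n_clusters,
        covariance_type="full",
        n_init=n_init,
        random_state=seed,
        reg_covar=1e-6,
    )
    try:
        gmm.fit(X)
    except ValueError as e:
        raise ValidationError(f"Gaussian mixture fit failed: {e}") from e
    post = gmm.predict_proba(X)
    labels = post.argmax(axis=1)
    ll = float(gmm.score(X) * X.shape[0])
    bic = float(gmm.bic(X))
    logger.info(
        "GMM-LE: %d clusters, log-likelihood %.2f, BIC %.2f",
        n_clusters, ll, bic,
    )
    return ClusterAssignment(
        labels=labels, posteriors=post, log_likelihood=ll, bic=bic
    )


def bic_scan(
    E: Embedding, candidates: list[int], seed: int = 0
) -> dict[int, float]:
    """BIC for each candidate cluster count (lower is better)."""
    out = {}
    for k in candidates:
        out[k] = gmm_le_cluster(E, k, seed=seed).bic
    return out


def score_marker_sets(
    Y: LabeledCellMatrix,
    assignment: ClusterAssignment,
    markers: MarkerSets,
) -> pd.DataFrame:
    """Mean log1p expression of each marker set within each cluster.

    Returns a clusters x marker-sets table; each cluster's provisional name
    (argmax set) is recorded in ``assignment.cluster_names``, with ties or
    all-zero rows flagged ambiguous.
    """
    resolved = markers.resolve(Y.feature_ids)
    logY = np.log1p(Y.values)
    clusters = sorted(set(int(l) for l in assignment.labels))
    table = pd.DataFrame(
        index=pd.Index(clusters, name="cluster"),
        columns=list(resolved),
        dtype=float,
    )
    for c in clusters:
        cells = np.flatnonzero(assignment.labels == c)
        for name, rows in resolved.items():
            per_cell = logY[np.ix_(rows, cells)].mean(axis=0)
            table.loc[c, name] = float(per_cell.mean())
    names: dict[int, str] = {}
    for c in clusters:
        row = table.loc[c]
        if row.max() == 0 or (row == row.max()).sum() > 1:
            names[c] = "ambiguous"
            logger.warning("cluster %d naming is ambiguous", c)
        else:
            names[c] = str(row.idxmax())
    assignment.cluster_names = names
    return table
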
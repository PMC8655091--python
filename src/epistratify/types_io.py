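"""Domain types and text-format I/O.

The deconvolution model is ``X = A W + eps``: a features-by-samples bulk
observation matrix ``X`` (DNA methylation beta values in [0,1], or RNA
expression), a features-by-cell-types reference matrix ``A`` of expected
per-cell-type profiles over discriminative features, and a cell-types-by-
samples mixing matrix ``W`` of proportions.  This module houses the typed
containers for each of these, the labelled single-cell matrix used to
estimate ``A``, marker-gene sets, and the plain-text readers/writers
(TSV/CSV for dense matrices, MatrixMarket triplets for sparse single-cell
counts).

Conventions: matrices are feature-major (features are rows) throughout;
missing values are encoded as ``NA`` in text and tracked in a boolean mask
separate from the numeric storage; text I/O is UTF-8, tab-delimited with
comma autodetection.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread

logger = logging.getLogger("epistratify")

MISSING_TOKEN = "NA"


class ValidationError(ValueError):
    """An input violated a domain-type invariant."""


class Modality(str, enum.Enum):
    """Measurement scale of a feature matrix."""

    DNAME_BETA = "dname_beta"  # methylation rates, values in [0,1]
    RNA_COUNTS = "rna_counts"  # non-negative read/UMI counts
    RNA_LOG = "rna_log"  # log-scale expression, unconstrained


def _check_unique(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate {what}: {dup!r}")


def _as_float_matrix(values, nrow: int, ncol: int, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (nrow, ncol):
        raise ValidationError(
            f"{what} has shape {arr.shape}, expected {(nrow, ncol)}"
        )
    return arr


@dataclass
class FeatureMatrix:
    """Features x samples observations (bulk ``X``, or purified profiles).

    ``missing`` marks entries that are absent (written as ``NA`` on disk);
    masked entries are not subject to the modality range checks.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    modality: Modality
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.modality = Modality(self.modality)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.feature_ids, "feature ID")
        _check_unique(self.sample_ids, "sample ID")
        self.values = _as_float_matrix(
            self.values, len(self.feature_ids), len(self.sample_ids), "values"
        )
        if self.missing is None:
            self.missing = np.zeros(self.values.shape, dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.values.shape:
                raise ValidationError("missing mask shape mismatch")
        # NaNs in the numeric storage are promoted into the mask.
        nan = np.isnan(self.values)
        if nan.any():
            self.missing = self.missing | nan
            self.values = np.where(nan, 0.0, self.values)
        obs = ~self.missing
        if not np.isfinite(self.values[obs]).all():
            raise ValidationError("non-finite value outside the missing mask")
        self._check_range(obs)

    def _check_range(self, obs: np.ndarray) -> None:
        if self.modality is Modality.DNAME_BETA:
            bad = obs & ((self.values < 0.0) | (self.values > 1.0))
            if bad.any():
                i, j = map(int, np.argwhere(bad)[0])
                raise ValidationError(
                    f"beta value {self.values[i, j]!r} outside [0,1] at "
                    f"feature {self.feature_ids[i]!r}, sample {self.sample_ids[j]!r}"
                )
        elif self.modality is Modality.RNA_COUNTS:
            bad = obs & (self.values < 0.0)
            if bad.any():
                i, j = map(int, np.argwhere(bad)[0])
                raise ValidationError(
                    f"negative count at feature {self.feature_ids[i]!r}, "
                    f"sample {self.sample_ids[j]!r}"
                )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        vals = np.where(self.missing, np.nan, self.values)
        return pd.DataFrame(vals, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class ReferenceMatrix:
    """Selected features x cell types profile matrix ``A``.

    Requires at least as many features as cell types, distinct columns and
    full column rank; the condition number is logged at construction because
    a poorly conditioned reference makes the mixing weights unstable.
    """

    values: np.ndarray
    feature_ids: list[str]
    cell_type_names: list[str]
    modality: Modality

    def __post_init__(self) -> None:
        self.modality = Modality(self.modality)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.cell_type_names = [str(c) for c in self.cell_type_names]
        _check_unique(self.feature_ids, "feature ID")
        _check_unique(self.cell_type_names, "cell type name")
        self.values = _as_float_matrix(
            self.values, len(self.feature_ids), len(self.cell_type_names), "values"
        )
        if not np.isfinite(self.values).all():
            raise ValidationError("reference matrix contains non-finite values")
        p, k = self.values.shape
        if p < k:
            raise ValidationError(f"need features >= cell types, got {p} < {k}")
        if self.modality is Modality.DNAME_BETA and (
            (self.values < 0).any() or (self.values > 1).any()
        ):
            raise ValidationError("beta reference values outside [0,1]")
        for a in range(k):
            for b in range(a + 1, k):
                if np.array_equal(self.values[:, a], self.values[:, b]):
                    raise ValidationError(
                        f"cell-type columns {self.cell_type_names[a]!r} and "
                        f"{self.cell_type_names[b]!r} are identical"
                    )
        rank = np.linalg.matrix_rank(self.values)
        if rank < k:
            raise ValidationError(
                f"reference matrix is column-rank deficient (rank {rank} < {k})"
            )
        self.condition_number = float(np.linalg.cond(self.values))
        logger.info(
            "reference matrix %dx%d, condition number %.3g",
            p, k, self.condition_number,
        )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_cell_types(self) -> int:
        return len(self.cell_type_names)


@dataclass
class MixingMatrix:
    """Cell types x samples estimated proportions ``W``.

    ``inestimable`` flags proportions the pipeline could not report (robust
    fit non-convergence, or total zeroing by the adaptive noise threshold).
    Unflagged columns are column-stochastic.
    """

    values: np.ndarray
    cell_type_names: list[str]
    sample_ids: list[str]
    inestimable: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cell_type_names = [str(c) for c in self.cell_type_names]
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.cell_type_names, "cell type name")
        _check_unique(self.sample_ids, "sample ID")
        self.values = _as_float_matrix(
            self.values, len(self.cell_type_names), len(self.sample_ids), "values"
        )
        if self.inestimable is None:
            self.inestimable = np.zeros(self.values.shape, dtype=bool)
        else:
            self.inestimable = np.asarray(self.inestimable, dtype=bool)
            if self.inestimable.shape != self.values.shape:
                raise ValidationError("inestimable mask shape mismatch")
        ok = ~self.inestimable
        if ((self.values[ok] < 0) | (self.values[ok] > 1)).any():
            raise ValidationError("proportion outside [0,1]")
        clean_cols = ~self.inestimable.any(axis=0)
        if clean_cols.any():
            sums = self.values[:, clean_cols].sum(axis=0)
            off = np.abs(sums - 1.0)
            if (off > 1e-8).any():
                j = int(np.flatnonzero(clean_cols)[np.argmax(off)])
                raise ValidationError(
                    f"column {self.sample_ids[j]!r} sums to "
                    f"{self.values[:, j].sum()!r}, expected 1"
                )


@dataclass
class LabeledCellMatrix:
    """Features x cells single-cell matrix ``Y`` with optional type labels.

    Labels, when present, must cover at least two cell types with at least
    two cells each, so that out-group covariances are estimable.
    """

    values: np.ndarray
    feature_ids: list[str]
    cell_ids: list[str]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        _check_unique(self.feature_ids, "feature ID")
        _check_unique(self.cell_ids, "cell ID")
        self.values = _as_float_matrix(
            self.values, len(self.feature_ids), len(self.cell_ids), "values"
        )
        if not np.isfinite(self.values).all():
            raise ValidationError("single-cell matrix contains non-finite values")
        if (self.values < 0).any():
            raise ValidationError("single-cell matrix contains negative values")
        if self.labels is not None:
            self.labels = [str(x) for x in self.labels]
            if len(self.labels) != len(self.cell_ids):
                raise ValidationError("one label per cell required")
            counts = pd.Series(self.labels).value_counts()
            if len(counts) < 2:
                raise ValidationError("labels must cover at least 2 cell types")
            small = counts[counts < 2]
            if len(small):
                raise ValidationError(
                    f"cell type(s) with < 2 cells: {', '.join(small.index)}"
                )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def cell_types(self) -> list[str]:
        if self.labels is None:
            raise ValidationError("matrix carries no cell-type labels")
        return sorted(set(self.labels))

    def cells_of_type(self, cell_type: str) -> np.ndarray:
        """Column indices of the cells labelled ``cell_type``."""
        if self.labels is None:
            raise ValidationError("matrix carries no cell-type labels")
        idx = np.array([i for i, l in enumerate(self.labels) if l == cell_type])
        if idx.size == 0:
            raise ValidationError(f"unknown cell type {cell_type!r}")
        return idx


@dataclass
class MarkerSets:
    """Mapping cell-type name -> marker gene identifiers."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        if not self.sets:
            raise ValidationError("no marker sets supplied")
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"marker set {name!r} is empty")

    def resolve(self, feature_ids: list[str]) -> dict[str, list[int]]:
        """Row indices of each set's markers; unresolved ones logged and dropped."""
        pos = {f: i for i, f in enumerate(feature_ids)}
        out: dict[str, list[int]] = {}
        for name, genes in self.sets.items():
            hit = [pos[g] for g in genes if g in pos]
            lost = [g for g in genes if g not in pos]
            if lost:
                logger.warning(
                    "marker set %s: %d/%d markers unresolved (%s)",
                    name, len(lost), len(genes), ", ".join(lost[:5]),
                )
            if not hit:
                raise ValidationError(
                    f"marker set {name!r} has no resolvable markers"
                )
            out[name] = hit
        return out


# ---------------------------------------------------------------------------
# Readers and writers
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(
        path, sep=sep, index_col=0, na_values=[MISSING_TOKEN],
        keep_default_na=False, encoding="utf-8",
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_feature_matrix(path, modality: Modality | str) -> FeatureMatrix:
    """Read a dense TSV/CSV (header = sample IDs, first column = feature IDs)."""
    df = _read_table(path)
    vals = df.to_numpy(dtype=float)
    return FeatureMatrix(
        values=vals,
        feature_ids=list(df.index),
        sample_ids=list(df.columns),
        modality=Modality(modality),
    )


def write_feature_matrix(X: FeatureMatrix, path) -> None:
    X.to_frame().to_csv(path, sep="\t", na_rep=MISSING_TOKEN, encoding="utf-8")


def read_reference_matrix(path, modality: Modality | str) -> ReferenceMatrix:
    df = _read_table(path)
    return ReferenceMatrix(
        values=df.to_numpy(dtype=float),
        feature_ids=list(df.index),
        cell_type_names=list(df.columns),
        modality=Modality(modality),
    )


def write_reference_matrix(A: ReferenceMatrix, path) -> None:
    pd.DataFrame(
        A.values, index=A.feature_ids, columns=A.cell_type_names
    ).to_csv(path, sep="\t", encoding="utf-8")


def read_mixing_matrix(path) -> MixingMatrix:
    df = _read_table(path)
    vals = df.to_numpy(dtype=float)
    flags = np.isnan(vals)
    return MixingMatrix(
        values=np.where(flags, 0.0, vals),
        cell_type_names=list(df.index),
        sample_ids=list(df.columns),
        inestimable=flags,
    )


def write_mixing_matrix(W: MixingMatrix, path) -> None:
    """TSV with cell types as rows, samples as columns; flags become ``NA``."""
    vals = np.where(W.inestimable, np.nan, W.values)
    pd.DataFrame(
        vals, index=W.cell_type_names, columns=W.sample_ids
    ).to_csv(path, sep="\t", na_rep=MISSING_TOKEN, encoding="utf-8")


def read_labeled_cells(
    matrix_path,
    features_path=None,
    barcodes_path=None,
    labels_path=None,
) -> LabeledCellMatrix:
    """Read a single-cell matrix: MTX triplet + sidecars, or dense TSV/CSV.

    The MTX file stores features as rows and cells as columns, with implicit
    zeros densified on read.  ``labels_path`` is a headerless one- or
    two-column TSV (cell label, or cell ID then label).
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        if features_path is None or barcodes_path is None:
            raise ValidationError("MTX input requires features and barcodes files")
        mat = mmread(matrix_path)
        if sparse.issparse(mat):
            mat = mat.toarray()
        feats = [l.split("\t")[0] for l in _read_lines(features_path)]
        cells = [l.split("\t")[0] for l in _read_lines(barcodes_path)]
        values = np.asarray(mat, dtype=float)
    else:
        df = _read_table(matrix_path)
        values = df.to_numpy(dtype=float)
        feats = list(df.index)
        cells = list(df.columns)
    labels = None
    if labels_path is not None:
        rows = [l.split("\t") for l in _read_lines(labels_path)]
        if rows and len(rows[0]) >= 2:
            by_cell = {r[0]: r[1] for r in rows}
            try:
                labels = [by_cell[c] for c in cells]
            except KeyError as e:
                raise ValidationError(f"no label for cell {e.args[0]!r}") from e
        else:
            labels = [r[0] for r in rows]
            if len(labels) != len(cells):
                raise ValidationError(
                    f"{len(labels)} labels for {len(cells)} cells"
                )
    return LabeledCellMatrix(
        values=values, feature_ids=feats, cell_ids=cells, labels=labels
    )


def _read_lines(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def write_labeled_cells_mtx(Y: LabeledCellMatrix, prefix) -> None:
    """Write ``<prefix>.mtx`` plus features/barcodes (and labels) sidecars."""
    from scipy.io import mmwrite

    prefix = Path(prefix)
    mmwrite(str(prefix) + ".mtx", sparse.coo_matrix(Y.values))
    _write_lines(str(prefix) + ".features.tsv", Y.feature_ids)
    _write_lines(str(prefix) + ".barcodes.tsv", Y.cell_ids)
    if Y.labels is not None:
        _write_lines(
            str(prefix) + ".labels.tsv",
            [f"{c}\t{l}" for c, l in zip(Y.cell_ids, Y.labels)],
        )


def _write_lines(path, lines) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in lines:
            fh.write(f"{line}\n")


def read_marker_sets(path) -> MarkerSets:
    """Two-column TSV/CSV: cell_type <sep> gene (no header required)."""
    path = Path(path)
    sep = _sniff_sep(path)
    sets: dict[str, list[str]] = {}
    for line in _read_lines(path):
        parts = line.split(sep)
        if len(parts) < 2:
            raise ValidationError(f"marker line needs 2 columns: {line!r}")
        ct, gene = parts[0].strip(), parts[1].strip()
        if ct.lower() == "cell_type" and gene.lower() == "gene":
            continue  # tolerated header
        sets.setdefault(ct, []).append(gene)
    return MarkerSets(sets)
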
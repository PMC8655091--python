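"""Quantile-matching augmentation of bulk purified-cell references.

Single-cell reference panels for some lineages (e.g. adipose, stroma) may
only exist as bulk RNA-seq profiles, whose value distribution differs
sharply from a single-cell library (depth, zero inflation).  To make such a
bulk profile commensurable with single-cell references, it is re-expressed
on the empirical distribution of a randomly sampled single-cell library:

    x_mapped_i = Fhat_b^{-1}[ Fhat_ref(x_ref_i) ]

where ``Fhat_ref`` is the right-continuous empirical CDF of the bulk
reference and ``Fhat_b^{-1}`` the type-1 (smallest-value) quantile inverse
of the sampled cell's library.  The mapping preserves the rank order of the
reference while drawing every output value from the sampled cell's value
multiset.  Repeating the draw ``B`` times yields a panel of synthetic
single-cell-like libraries per reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .types_io import FeatureMatrix, LabeledCellMatrix, ValidationError

logger = logging.getLogger("epistratify")


@dataclass
class AugmentedLibrarySet:
    """B synthetic libraries per source reference, with sampling provenance."""

    libraries: dict[str, np.ndarray]  # reference name -> genes x B matrix
    feature_ids: list[str]
    sampled_cell_ids: list[str]  # one per draw b
    seed: int


def quantile_map(x_ref: np.ndarray, sc_library: np.ndarray) -> np.ndarray:
    """Map a reference vector onto a single-cell library's quantiles.

    Right-continuous ECDF for the reference, type-1 inverse for the
    library: ties in ``x_ref`` map to equal outputs; a constant reference
    sits at quantile 1 and maps to the library maximum.
    """
    x_ref = np.asarray(x_ref, dtype=float)
    sc = np.asarray(sc_library, dtype=float)
    if x_ref.shape != sc.shape or x_ref.ndim != 1:
        raise ValidationError(
            f"length mismatch: reference {x_ref.shape}, library {sc.shape}"
        )
    p = x_ref.size
    sorted_ref = np.sort(x_ref)
    # right-continuous ECDF: F(x) = #{values <= x} / p, an integer rank / p
    rank = np.searchsorted(sorted_ref, x_ref, side="right")  # in 1..p
    sorted_sc = np.sort(sc)
    # type-1 inverse of q = r/p is the r-th smallest library value
    return sorted_sc[rank - 1]


def augment_reference_set(
    sc: LabeledCellMatrix,
    bulk_refs: FeatureMatrix,
    B: int = 100,
    seed: int = 0,
) -> AugmentedLibrarySet:
    """Build B quantile-mapped synthetic libraries per bulk reference.

    For each draw, one cell is sampled uniformly with replacement (seeded)
    and every bulk reference column is quantile-mapped onto it, over the
    intersection of gene sets.
    """
    if B < 1:
        raise ValidationError("B must be at least 1")
    spos = {f: i for i, f in enumerate(sc.feature_ids)}
    shared = [(i, spos[f]) for i, f in enumerate(bulk_refs.feature_ids)
              if f in spos]
    if not shared:
        raise ValidationError("no shared genes between references and cells")
    bi, si = map(np.array, zip(*shared))
    genes = [bulk_refs.feature_ids[i] for i in bi]
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, sc.n_cells, size=B)
    libs: dict[str, np.ndarray] = {}
    for r, name in enumerate(bulk_refs.sample_ids):
        ref_vec = bulk_refs.values[bi, r]
        cols = np.column_stack(
            [quantile_map(ref_vec, sc.values[si, d]) for d in draws]
        )
        zero_frac = float((cols == 0).mean())
        logger.info(
            "augmented %s: %d libraries over %d genes, %.1f%% zeros",
            name, B, len(genes), 100 * zero_frac,
        )
        libs[name] = cols
    return AugmentedLibrarySet(
        libraries=libs,
        feature_ids=genes,
        sampled_cell_ids=[sc.cell_ids[d] for d in draws],
        seed=seed,
    )
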
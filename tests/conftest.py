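import numpy as np
import pytest

from epistratify import (
    FeatureMatrix,
    LabeledCellMatrix,
    Modality,
    ReferenceMatrix,
    make_synthetic_reference,
    make_synthetic_sc,
)


@pytest.fixture
def beta_reference() -> ReferenceMatrix:
    """58x3 full-rank methylation reference with planted signature loci."""
    return make_synthetic_reference(p=58, k=3, separation=0.5, seed=1)


@pytest.fixture
def small_sc() -> LabeledCellMatrix:
    """Small labelled NB count matrix with 3 planted expression programs."""
    return make_synthetic_sc(m=60, p=80, k=3, effect=8.0, seed=3,
                             markers_per_type=10)


@pytest.fixture
def tiny_beta() -> FeatureMatrix:
    rng = np.random.default_rng(0)
    vals = rng.uniform(size=(6, 4))
    return FeatureMatrix(
        values=vals,
        feature_ids=[f"f{i}" for i in range(6)],
        sample_ids=[f"s{j}" for j in range(4)],
        modality=Modality.DNAME_BETA,
    )
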
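import numpy as np
import pytest

from mojknet.datatypes import Modality, OmicsMatrix
from mojknet.omics_io import filter_and_impute
from mojknet.synthdata import SynthSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Separable 3-class cohort, small enough for fast model tests."""
    spec = SynthSpec(
        n_samples=60,
        class_proportions=(0.5, 0.3, 0.2),
        feature_dims=(80, 80, 80, 24),
        effect_size=(1.0, 1.2, 1.5, 0.8),
        informative_frac=(0.2, 0.2, 0.2, 0.2),
        missing_rate=0.02,
        seed=11,
    )
    ds = generate_cohort(spec)
    for m in list(ds.omics):
        ds.omics[m] = filter_and_impute(ds.omics[m])
    return ds


@pytest.fixture
def toy_matrix():
    rng = np.random.default_rng(7)
    return OmicsMatrix(
        modality=Modality.MRNA,
        sample_ids=[f"S{i}" for i in range(6)],
        feature_ids=[f"g{j}" for j in range(4)],
        values=rng.normal(size=(6, 4)),
    )
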
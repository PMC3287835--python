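import numpy as np
import pandas as pd
import pytest

from qtdesign.cohort import reference_cohort


@pytest.fixture(scope="session")
def ref_cohort():
    """Deterministic 321-individual reference cohort, null trait, 200 reps."""
    return reference_cohort(trait_kind="null", n_replicates=200)


@pytest.fixture(scope="session")
def ref_genotypes(ref_cohort):
    return pd.DataFrame(ref_cohort.genotypes, columns=ref_cohort.snp_ids)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
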
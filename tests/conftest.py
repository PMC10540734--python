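import numpy as np
import pandas as pd
import pytest

from dielprot.io import QuantTable, SampleKey
from dielprot.simulate import SimSpec, generate_ld_dataset

LD_COLS = [f"LD_ZT{zt}_{rep}" for zt in (0, 4, 8, 12, 16, 20) for rep in "ABCDE"]


def make_table(values: np.ndarray, ids=None, columns=None) -> QuantTable:
    columns = columns or LD_COLS[: values.shape[1]]
    ids = ids or [f"f{i}" for i in range(values.shape[0])]
    return QuantTable(pd.DataFrame(values, index=pd.Index(ids, name="feature_id"), columns=columns))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_table(rng):
    """20 features x 30 LD samples of lognormal abundances."""
    vals = np.exp(rng.normal(5, 1, size=(20, 30)))
    return make_table(vals)


@pytest.fixture
def rhythmic_dataset():
    """200 features, half rhythmic with 3-fold amplitude, CV 0.1."""
    spec = SimSpec(n_features=200, frac_rhythmic=0.5, fold_range=(3.0, 3.0), noise_cv=0.1, seed=11)
    return generate_ld_dataset(spec)
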
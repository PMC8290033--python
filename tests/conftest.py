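import numpy as np
import pandas as pd
import pytest

from multibiodx import CHANNELS_1020, PLVMatrix
from multibiodx.feature_assembly import FeatureTable


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_plv():
    """Factory for random symmetric unit-diagonal weight matrices."""

    def make(seed=0, n=16, band="theta"):
        r = np.random.default_rng(seed)
        w = r.random((n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        names = list(CHANNELS_1020[:n]) if n <= 16 else [f"ch{i}" for i in range(n)]
        return PLVMatrix(values=w, band_label=band, n_epochs_averaged=1,
                         channel_names=names)

    return make


def make_feature_table(n_per_group=30, n_features=12, n_informative=4,
                       effect=1.0, seed=0, modality="Blood"):
    """Gaussian two-group feature table used across ML tests."""
    r = np.random.default_rng(seed)
    n = 2 * n_per_group
    X = r.standard_normal((n, n_features))
    groups = np.array(["SZ"] * n_per_group + ["HC"] * n_per_group)
    X[groups == "SZ", :n_informative] += effect
    idx = pd.Index([f"S{i:03d}" for i in range(n)], name="subject_id")
    data = pd.DataFrame(X, index=idx,
                        columns=[f"f{i:02d}" for i in range(n_features)])
    return FeatureTable(data=data, modality={c: modality for c in data.columns},
                        groups=pd.Series(groups, index=idx))


@pytest.fixture
def feature_table():
    return make_feature_table
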
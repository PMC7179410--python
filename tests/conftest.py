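import numpy as np
import pandas as pd
import pytest

from metabomark.io import FeatureTable
from metabomark.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def default_table_truth():
    """One default-config synthetic experiment shared across tests."""
    return generate(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def small_table_truth():
    """A small, fast synthetic experiment (24 + 16 samples, 60 features)."""
    cfg = SyntheticConfig(
        n_group_a=24, n_group_b=16, n_qc=6, n_features=60, n_markers=5, seed=7
    )
    return generate(cfg)


def make_table(abund, groups, mz=None, rt=None):
    """Build a FeatureTable from a plain dict/array spec (test helper)."""
    ab = pd.DataFrame(abund)
    ab.index = [f"s{i}" for i in range(len(ab))] if ab.index.dtype == np.int64 else ab.index
    g = pd.Series(groups, index=ab.index, name="group")
    mz = pd.Series(mz if mz is not None else np.arange(1.0, ab.shape[1] + 1),
                   index=ab.columns)
    rt = pd.Series(rt if rt is not None else np.linspace(1, 10, ab.shape[1]),
                   index=ab.columns)
    return FeatureTable(abundances=ab, groups=g, feature_mz=mz, feature_rt=rt)
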
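import numpy as np
import pandas as pd
import pytest

import coca


@pytest.fixture
def small_config():
    """A compact 5-subgroup study: fast, but fully structured."""
    return coca.SyntheticConfig(
        n_samples=150,
        n_subgroups=5,
        seed=7,
        cnv=coca.PlatformSpec(n_features=60, n_blocks=5, effect=0.5, noise_sd=0.25,
                              block_sd=0.0, baseline_sd=0.0),
        mrna=coca.PlatformSpec(n_features=120, n_blocks=10, effect=2.0,
                               baseline_mean=5.0, baseline_sd=2.0),
        mirna=coca.PlatformSpec(n_features=60, n_blocks=5, effect=2.0,
                                baseline_mean=6.0, baseline_sd=1.5),
        meth=coca.PlatformSpec(n_features=100, n_blocks=8, effect=2.0, baseline_sd=1.5),
    )


@pytest.fixture
def small_dataset(small_config):
    return coca.simulate_multiomics(small_config)


@pytest.fixture
def two_block_coc():
    """A COC matrix with two perfectly separated 20-sample blocks."""
    samples = [f"A{i}" for i in range(20)] + [f"B{i}" for i in range(20)]
    rows = []
    for r in range(6):
        labels = pd.Series([1.0] * 20 + [0.0] * 20, index=samples)
        rows.append(coca.IndicatorRow("mrna", r + 1, labels))
    return coca.assemble_coc_matrix(rows, samples), samples


def make_platform(values, kind="mrna", state="preprocessed", features=None, samples=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return coca.PlatformMatrix(kind, pd.DataFrame(values, index=features, columns=samples), state)
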
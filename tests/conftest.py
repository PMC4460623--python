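import numpy as np
import pandas as pd
import pytest

from drivernet import synthetic


@pytest.fixture(scope="session")
def synth():
    """Default synthetic cohort, seed 1 (shared; treat as read-only)."""
    return synthetic.generate_cohort(seed=1)


@pytest.fixture(scope="session")
def fixture_dir(synth, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    synthetic.write_fixture(synth, out)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def two_group_frame():
    """Tiny 4-feature matrix with an obvious differential feature."""
    samples = [f"T{i}" for i in range(5)] + [f"N{i}" for i in range(5)]
    groups = pd.Series(["tumor"] * 5 + ["normal"] * 5, index=samples)
    rs = np.random.default_rng(7)
    data = rs.normal(size=(4, 10))
    data[0, :5] += 4.0  # strong up in tumor
    return pd.DataFrame(data, index=[f"g{i}" for i in range(4)], columns=samples), groups
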
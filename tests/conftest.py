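import numpy as np
import pandas as pd
import pytest

from seepbef import AbundanceMatrix, SimConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset shared by read-only tests."""
    return generate_dataset(SimConfig(seed=7))


@pytest.fixture
def tiny_abundance():
    counts = pd.DataFrame(
        [[5, 3, 2], [0, 0, 7], [1, 1, 1]],
        index=pd.Index(["s1", "s2", "s3"], name="sample"),
        columns=["spA", "spB", "spC"],
    )
    return AbundanceMatrix(counts, {"spA": "F1", "spB": "F1", "spC": "F2"})


@pytest.fixture
def tiny_traits():
    # two families, 32 traits; F1 scores trait t01 with 5, F2 scores t02 with 1
    names = [f"t{i:02d}" for i in range(1, 33)]
    traits = pd.DataFrame(0, index=pd.Index(["F1", "F2"], name="family"), columns=names)
    traits.loc["F1", "t01"] = 5
    traits.loc["F2", "t02"] = 1
    return traits


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
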
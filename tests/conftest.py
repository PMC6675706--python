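import numpy as np
import pandas as pd
import pytest

from cernascreen import ExpressionMatrix, MatureMiRNA, SimConfig, simulate_cerna_dataset


@pytest.fixture
def mir219() -> MatureMiRNA:
    """The mature miR-219a-5p guide strand used in the worked examples."""
    from cernascreen import MIR_219A_5P

    return MIR_219A_5P


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    data = pd.DataFrame(
        [[1.0, 2.0, 3.0], [4.0, 0.0, 6.0]],
        index=["geneA", "geneB"],
        columns=["s1", "s2", "s3"],
    )
    return ExpressionMatrix(data, scale="linear")


@pytest.fixture(scope="session")
def planted_dataset():
    """One simulated 58-sample dataset with a single planted triplet."""
    config = SimConfig(rng_seed=11)
    lnc, mir, mrna, truth = simulate_cerna_dataset(config)
    return config, lnc, mir, mrna, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20210914)
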
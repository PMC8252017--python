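import numpy as np
import pandas as pd
import pytest

from phenoceiling.io_formats import read_newick
from phenoceiling.synthetic_data import SimulationConfig, simulate_fossil_scenario

#: balanced 8-taxon ultrametric tree, depth 3: sibling pairs share 2/3 of
#: their path to the root, within-quartet cousins 1/3, across the root 0.
BALANCED8 = "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);"

#: the 3-tip worked tree: ((A:1,B:1):1,C:2)
TRIPLE = "((A:1,B:1):1,C:2);"


@pytest.fixture(scope="session")
def tree8():
    return read_newick(BALANCED8)


@pytest.fixture(scope="session")
def tree3():
    return read_newick(TRIPLE)


def balanced8_correlation() -> tuple[list[str], np.ndarray]:
    """Hand-constructed Brownian correlation matrix of BALANCED8,
    independent of the package's tree traversal."""
    labels = list("ABCDEFGH")
    C = np.zeros((8, 8))
    for i in range(8):
        for j in range(8):
            if i == j:
                C[i, j] = 1.0
            elif i // 2 == j // 2:        # sibling pair, MRCA depth 2/3
                C[i, j] = 2.0 / 3.0
            elif i // 4 == j // 4:        # same quartet, MRCA depth 1/3
                C[i, j] = 1.0 / 3.0
    return labels, C


@pytest.fixture(scope="session")
def scenario():
    """Default synthetic fossil scenario (ceiling-tracking lagomorphs)."""
    return simulate_fossil_scenario(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def noiseless_scenario():
    """Zero age-uncertainty, zero mass-error scenario: the pipeline must
    reproduce the generating values exactly."""
    cfg = SimulationConfig(seed=5, mass_se=0.0)
    return simulate_fossil_scenario(cfg, tracking_noise_sd=0.0,
                                    age_halfwidth=0.0)


def series_from_traits(df: pd.DataFrame, value_col: str) -> pd.Series:
    return pd.Series(df[value_col].to_numpy(), index=df["species"].to_numpy())
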
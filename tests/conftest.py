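import numpy as np
import pandas as pd
import pytest

from methpattern import BetaMatrix, simulate_cohort


@pytest.fixture
def tiny_matrix() -> BetaMatrix:
    """6 CpGs x 4 samples with two clear CpG groups (low vs high beta)."""
    vals = np.array(
        [
            [0.10, 0.12, 0.08, 0.11],
            [0.09, 0.10, 0.12, 0.10],
            [0.11, 0.09, 0.10, 0.12],
            [0.90, 0.88, 0.91, 0.89],
            [0.92, 0.90, 0.89, 0.91],
            [0.88, 0.91, 0.90, 0.90],
        ]
    )
    return BetaMatrix(
        pd.DataFrame(
            vals,
            index=[f"cg{i}" for i in range(6)],
            columns=[f"S{j}" for j in range(4)],
        )
    )


@pytest.fixture(scope="session")
def small_cohort():
    """800 CpGs x 100 samples with default planted geometry."""
    return simulate_cohort(n_cpgs=800, n_samples=100, seed=3)


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort: 5,000 CpGs x 180 samples, seed 1."""
    return simulate_cohort(seed=1)
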
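import numpy as np
import pandas as pd
import pytest

from cpgsig import (MethylationMatrix, SampleLabels, SyntheticConfig, generate)


@pytest.fixture
def tiny_matrix():
    """3 CpGs x 4 samples, complete, hand-checkable values."""
    data = pd.DataFrame(
        [[0.1, 0.2, 0.8, 0.9],
         [0.5, 0.5, 0.5, 0.5],
         [0.2, 0.4, 0.6, 0.3]],
        index=["cg000", "cg001", "cg002"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return MethylationMatrix(data)


@pytest.fixture
def tiny_labels():
    return SampleLabels(("s1", "s2", "s3", "s4"), (0, 0, 1, 1))


@pytest.fixture(scope="session")
def desk_dataset():
    """Desk-scale study replica: 5,000 CpGs, 200 planted (delta 0.15), 44/44/44."""
    return generate(SyntheticConfig(seed=20230501))


@pytest.fixture(scope="session")
def small_dataset():
    """Small planted-signal dataset shared by the faster classifier tests."""
    return generate(SyntheticConfig(n_cpgs=400, n_informative=40, delta=0.2,
                                    missing_rate=0.005, seed=7))
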
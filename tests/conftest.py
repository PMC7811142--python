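import numpy as np
import pandas as pd
import pytest

from viroflux.compositional import AbundanceMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def toy_abundance():
    """8 markers x 10 samples with hand-set counts for filter tests.

    Marker layout (presence = count >= 2):
      m0: present in all 10 samples, counts increase with sample index
      m1: present in all 10, counts decrease with sample index
      m2: present in only 4 samples (fails the occurrence gate)
      m3: present in 10 but constant (correlation undefined -> excluded)
      m4: present in 6, weak association
      m5: present in 10, counts shuffled (no association)
      m6: single-read occurrences only (presence needs >= 2 reads)
      m7: RdRP marker present in all 10, increasing
    """
    counts = pd.DataFrame(
        {
            f"s{j}": col
            for j, col in enumerate(
                np.array(
                    [
                        [2, 3, 4, 6, 8, 10, 13, 16, 20, 25],   # m0
                        [25, 20, 16, 13, 10, 8, 6, 4, 3, 2],   # m1
                        [5, 9, 0, 0, 0, 0, 0, 0, 7, 3],        # m2
                        [4, 4, 4, 4, 4, 4, 4, 4, 4, 4],        # m3
                        [0, 2, 0, 3, 0, 2, 0, 4, 2, 3],        # m4
                        [7, 2, 9, 3, 8, 2, 6, 4, 9, 2],        # m5
                        [1, 1, 1, 1, 1, 1, 1, 1, 1, 1],        # m6
                        [2, 2, 3, 4, 5, 7, 9, 12, 15, 18],     # m7
                    ]
                ).T
            )
        },
        index=[f"m{i}" for i in range(8)],
    )
    classes = pd.Series(
        ["PolB"] * 7 + ["RdRP"], index=counts.index
    )
    lengths = pd.Series([1000] * 8, index=counts.index)
    return AbundanceMatrix(
        counts=counts, marker_class=classes, gene_length=lengths
    )


@pytest.fixture
def toy_cee():
    return pd.Series(
        [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0],
        index=[f"s{j}" for j in range(10)],
    )
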
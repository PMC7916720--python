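import numpy as np
import pandas as pd
import pytest

from planktonic.io import CommunityTable


@pytest.fixture
def tiny_table() -> CommunityTable:
    """2 samples x 3 OTUs, sample sums (6, 4)."""
    return CommunityTable(pd.DataFrame(
        [[5, 0, 1], [0, 2, 2]], index=["A", "B"], columns=["o1", "o2", "o3"]))


@pytest.fixture
def grouped_table() -> tuple[CommunityTable, dict[str, str]]:
    """6 samples in two cleanly separated composition groups."""
    counts = pd.DataFrame(
        [[90, 10, 0, 0],
         [85, 15, 0, 0],
         [80, 18, 2, 0],
         [0, 0, 12, 88],
         [0, 2, 10, 88],
         [0, 0, 15, 85]],
        index=[f"s{i}" for i in range(6)],
        columns=[f"o{i}" for i in range(4)])
    groups = {f"s{i}": ("x" if i < 3 else "y") for i in range(6)}
    return CommunityTable(counts), groups


def random_table(rng: np.random.Generator, n_samples: int = 5,
                 n_otus: int = 8, max_count: int = 40) -> CommunityTable:
    counts = rng.integers(0, max_count, size=(n_samples, n_otus))
    counts[:, 0] += 1  # keep every row non-empty
    return CommunityTable(pd.DataFrame(
        counts, index=[f"s{i}" for i in range(n_samples)],
        columns=[f"o{i}" for i in range(n_otus)]))
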
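import numpy as np
import pandas as pd
import pytest

from phiclust.io import CountMatrix


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """3 genes x 2 cells, hand-checkable."""
    return CountMatrix(
        np.array([[0, 1], [2, 3], [0, 2]]),
        ["g1", "g2", "g3"],
        ["c1", "c2"],
    )


@pytest.fixture
def random_counts() -> CountMatrix:
    """Poisson counts, 60 genes x 40 cells, fixed seed."""
    rng = np.random.default_rng(42)
    vals = rng.poisson(5.0, size=(60, 40))
    return CountMatrix(
        vals,
        [f"g{i}" for i in range(60)],
        [f"c{i}" for i in range(40)],
    )


@pytest.fixture
def noise_350x201() -> np.ndarray:
    """Standard-normal matrix at the default planted-signal geometry."""
    return np.random.default_rng(7).standard_normal((350, 201))


@pytest.fixture
def labels_two(random_counts) -> pd.Series:
    half = random_counts.n_cells // 2
    return pd.Series(
        ["a"] * half + ["b"] * (random_counts.n_cells - half),
        index=random_counts.cell_ids,
        name="cluster",
    )
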
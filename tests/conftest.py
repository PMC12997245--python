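import numpy as np
import pandas as pd
import pytest

from ilqsar.descriptors import DescriptorTable, bin_label


def make_table(n_rows: int, names: list[str], seed: int = 0,
               beta: np.ndarray | None = None, intercept: float = 0.0,
               noise_sd: float = 0.0) -> DescriptorTable:
    """Small random descriptor table with an optional planted response."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.0, 20.0, size=(n_rows, len(names)))
    ids = [f"IL{i + 1}" for i in range(n_rows)]
    data = pd.DataFrame(X, index=ids, columns=names)
    response = None
    if beta is not None:
        y = X @ np.asarray(beta, dtype=float) + intercept
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=n_rows)
        response = pd.Series(y, index=ids)
    return DescriptorTable(data=data, response=response)


@pytest.fixture
def cation_bins():
    return [bin_label("cation", s / 1000) for s in range(-8, 9, 4)]  # 5 bins


@pytest.fixture
def small_planted_table(cation_bins):
    beta = np.array([0.5, -0.3, 0.2, 0.4, -0.25])
    return make_table(30, cation_bins, seed=42, beta=beta,
                      intercept=-2.0, noise_sd=0.5), beta
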
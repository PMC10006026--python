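import numpy as np
import pandas as pd
import pytest

from gxestab import GenerativeModel, GxETable, simulate_genotypes, simulate_phenotypes


@pytest.fixture
def t1() -> GxETable:
    """Two genotypes in three environments, hand-checkable by arithmetic."""
    return GxETable(
        "yield",
        pd.DataFrame(
            [[4.0, 6.0, 8.0], [0.0, 6.0, 6.0]],
            index=["g1", "g2"],
            columns=["e1", "e2", "e3"],
        ),
    )


@pytest.fixture(scope="session")
def default_model() -> GenerativeModel:
    return GenerativeModel()


@pytest.fixture(scope="session")
def small_pool(default_model):
    """500 genotypes x 300 environments under generator defaults."""
    params = simulate_genotypes(default_model, 500, seed=20)
    return simulate_phenotypes(params, default_model, 300, seed=20)


def random_table(rng: np.random.Generator, g: int, e: int) -> GxETable:
    """Random positive complete table, suitable for every index."""
    data = rng.uniform(0.5, 10.0, size=(g, e))
    return GxETable(
        "yield",
        pd.DataFrame(
            data,
            index=[f"g{i}" for i in range(g)],
            columns=[f"e{j}" for j in range(e)],
        ),
    )
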
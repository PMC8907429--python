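import numpy as np
import pandas as pd
import pytest

from irgpi.io_core import ExpressionMatrix, SurvivalRecord
from irgpi.synthetic import SimulationConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_expr(rng):
    """A 30-gene x 12-sample continuous expression matrix (no ties)."""
    genes = [f"g{i:02d}" for i in range(30)]
    samples = [f"s{i:02d}" for i in range(12)]
    values = rng.lognormal(mean=2.0, sigma=1.0, size=(30, 12))
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), "fixture")


@pytest.fixture(scope="session")
def small_bundle():
    """A compact strong-signal three-cohort bundle shared across tests."""
    cfg = SimulationConfig(
        seed=123, n_genes=40, n_samples=(40, 30, 30), pair_flip_probability=0.05
    )
    return generate(cfg)


def make_survival(times, events, responses=None, prefix="p"):
    responses = responses or [None] * len(times)
    return [
        SurvivalRecord(f"{prefix}{i}", float(t), int(e), response=r)
        for i, (t, e, r) in enumerate(zip(times, events, responses))
    ]
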
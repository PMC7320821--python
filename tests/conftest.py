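import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

TISSUES = ["t1", "t2", "t3", "t4", "t5", "t6", "t7"]


@pytest.fixture(scope="session")
def small_dataset():
    """One default-shaped synthetic dataset shared across read-only tests."""
    from omicforge import simulate

    config = simulate.default_config(seed=11, n_contigs=20)
    em, annot, mm, contigs, truth = simulate.generate_dataset(config)
    return {
        "config": config,
        "expression": em,
        "annotation": annot,
        "metabolites": mm,
        "contigs": contigs,
        "truth": truth,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_expression(rng, n_genes=20, n_tissues=7, prefix="g"):
    values = np.exp(rng.normal(2.0, 1.0, size=(n_genes, n_tissues)))
    return pd.DataFrame(
        values,
        index=[f"{prefix}{i}" for i in range(n_genes)],
        columns=TISSUES[:n_tissues],
    )
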
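import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from crossde import ExpressionTable, SimulationConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=11)


@pytest.fixture
def small_config() -> SimulationConfig:
    """Desk-scale config for fast structural tests."""
    return SimulationConfig(
        seed=7,
        n_genes=300,
        n_go_terms=10,
        n_planted_terms=2,
        genes_per_term=8,
        n_human_de_per_celltype=30,
    )


def random_expression_table(rng: np.random.Generator, n_genes: int = 40, k: int = 5) -> ExpressionTable:
    """A random two-group table with no true signal (oracle fodder)."""
    values = rng.normal(5.0, 1.0, (n_genes, 2 * k))
    return ExpressionTable(
        gene_ids=[f"g{i}" for i in range(n_genes)],
        sample_ids=[f"s{i}" for i in range(2 * k)],
        values=values,
        group=np.array(["control"] * k + ["treated"] * k, dtype=object),
        detected=np.ones(n_genes, dtype=bool),
    )
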
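import numpy as np
import pandas as pd
import pytest

from sigbench import (
    BalancingConfig,
    GeneMatrix,
    default_signature_set,
    generate_compendium,
    score_compendium,
)
from sigbench.simulate import small_config


@pytest.fixture(scope="session")
def defs():
    return default_signature_set()


@pytest.fixture(scope="session")
def small_comp():
    """A desk-scale synthetic compendium shared across tests (read-only)."""
    return generate_compendium(small_config(), seed=11)


@pytest.fixture(scope="session")
def small_scoring(small_comp):
    return score_compendium(
        small_comp.probe_matrices,
        small_comp.clinical,
        small_comp.definitions,
        balancing=BalancingConfig(seed=11),
    )


def make_gene_matrix(values: dict[str, list[float]], samples: list[str], dataset_id="dstest", er=None):
    """Tiny genes × samples matrix from a {gene: row} dict."""
    df = pd.DataFrame.from_dict(values, orient="index", columns=samples, dtype=float)
    er_series = pd.Series(er, index=samples) if er is not None else None
    return GeneMatrix(dataset_id=dataset_id, values=df, er_status=er_series)
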
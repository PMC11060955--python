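import numpy as np
import pandas as pd
import pytest

from tempro.config import SimulationConfig
from tempro import synthetic


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_genes=60, seed=1)


@pytest.fixture(scope="session")
def small_study(small_config):
    """Expression matrix + peptide evidence sharing one small design."""
    expr, gt_expr = synthetic.simulate_expression(small_config)
    evidence, gt_pep = synthetic.simulate_peptides(small_config)
    return expr, gt_expr, evidence, gt_pep


@pytest.fixture(scope="session")
def tumor_only_config():
    return SimulationConfig(
        n_genes=200, tissues=("tumor",), tissue_unique_fraction=0.0,
        intensity_log_sd=0.2, seed=5,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def match_labels(truth: pd.Series, predicted: pd.Series) -> float:
    """Fraction of agreeing hard assignments after optimal label matching."""
    from scipy.optimize import linear_sum_assignment

    t = pd.Categorical(truth)
    p = pd.Categorical(predicted)
    C = np.zeros((len(t.categories), len(p.categories)))
    for a, b in zip(t.codes, p.codes):
        C[a, b] += 1
    r, c = linear_sum_assignment(-C)
    return float(C[r, c].sum() / len(truth))
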
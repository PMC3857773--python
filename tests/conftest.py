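import logging

import numpy as np
import pytest

from netmra.core import ExpressionMatrix, GeneSet, SurvivalTable

logging.disable(logging.INFO)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_expr():
    return ExpressionMatrix(
        ["G1", "G2"], ["S1", "S2", "S3"], np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
    )


@pytest.fixture
def toy_survival():
    # 3 subjects, events at t=1,2,3, no censoring
    return SurvivalTable(["a", "b", "c"], [1.0, 2.0, 3.0], [1, 1, 1], [0.1, 0.2, 0.3])


def make_survival(times, events, covariates=None):
    n = len(times)
    cov = covariates if covariates is not None else [0.0] * n
    return SurvivalTable([f"s{i}" for i in range(n)], times, events, cov)


@pytest.fixture
def gene_sets():
    return [
        GeneSet("S1", "first", ["G1", "G2", "G3"]),
        GeneSet("S2", "second", ["G2", "G3", "G4"]),
    ]
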
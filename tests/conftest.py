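import numpy as np
import pandas as pd
import pytest

from mmpscore import CohortSpec, ExpressionMatrix, GeneSet, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest planted cohort shared across read-only tests."""
    return generate_cohort(CohortSpec(n_samples=150, seed=0))


@pytest.fixture(scope="session")
def panel_geneset(small_cohort):
    return GeneSet("panel", frozenset(small_cohort.truth["cluster_genes"]))


@pytest.fixture()
def tiny_expr():
    """3 genes x 4 samples, fixed values."""
    return ExpressionMatrix(pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [4.0, 3.0, 2.0, 1.0],
         [1.5, 1.5, 1.5, 1.5]],
        index=["G1", "G2", "G3"], columns=["S1", "S2", "S3", "S4"],
    ))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
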
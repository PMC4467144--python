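import numpy as np
import pandas as pd
import pytest

from etstargets import (
    CellLineModel,
    ExpressionMatrix,
    Population,
    gen_cellline_experiment,
    gen_tumor_cohort,
    study_cohort_truth,
    study_target_truth,
)


@pytest.fixture
def tiny_matrix():
    data = pd.DataFrame(
        [[8.0, 7.0, 6.9, 9.0, 9.1],
         [7.0, 7.6, 7.7, 7.0, 7.1],
         [6.0, 6.0, 6.0, 6.0, 6.0]],
        index=pd.Index(["GA", "GB", "GC"], name="gene_id"),
        columns=["ctrl", "p1", "p2", "q1", "q2"],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def two_clone_model():
    return CellLineModel(
        name="shETV1-LNCaP", ets="ETV1", kind="silencing",
        control=Population("shNeg", ("ctrl",), "control"),
        manipulated=(Population("C1", ("p1",), "manipulated"),
                     Population("C2", ("p2",), "manipulated")),
    )


@pytest.fixture(scope="session")
def study_experiment():
    """One seeded study-design experiment shared across tests."""
    truth = study_target_truth()
    matrix, models, truth = gen_cellline_experiment(
        n_genes=400, truth=truth, seed=11)
    return matrix, models, truth


@pytest.fixture(scope="session")
def study_cohort():
    return gen_tumor_cohort(study_cohort_truth(), seed=11, n_genes=30)
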
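import numpy as np
import pandas as pd
import pytest

from camta_drought import (ContrastSpec, ExperimentDesign, ExpressionMatrix,
                           SimulationConfig, differential_expression,
                           simulate_expression)


def make_design(tissues=("LEAF",), n_reps=3):
    rows = []
    for tissue in tissues:
        for genotype in ("WT", "MUT"):
            for condition in ("CONTROL", "DROUGHT"):
                for rep in range(1, n_reps + 1):
                    rows.append((f"{tissue}_{genotype}_{condition}_{rep}",
                                 genotype, condition, tissue, rep))
    return ExperimentDesign(pd.DataFrame(
        rows, columns=["sample_id", "genotype", "condition", "tissue",
                       "replicate"]))


@pytest.fixture
def small_design():
    return make_design()


@pytest.fixture
def small_matrix(small_design):
    rng = np.random.default_rng(7)
    data = rng.normal(8, 1, size=(4, len(small_design.sample_ids)))
    return ExpressionMatrix(pd.DataFrame(
        data, index=[f"g{i}" for i in range(1, 5)],
        columns=small_design.sample_ids))


@pytest.fixture(scope="session")
def leaf_simulation():
    """One moderately sized leaf-only simulation shared across tests."""
    config = SimulationConfig(n_genes=600, seed=42, tissues=("LEAF",))
    matrix, design, truth = simulate_expression(config)
    return config, matrix, design, truth


@pytest.fixture(scope="session")
def leaf_de_tables(leaf_simulation):
    _, matrix, design, _ = leaf_simulation
    de_wt = differential_expression(matrix, design, ContrastSpec("LEAF", "WT"))
    de_mut = differential_expression(matrix, design, ContrastSpec("LEAF", "MUT"))
    return de_wt, de_mut
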
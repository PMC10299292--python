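import numpy as np
import pytest

from coherence_screen.dataio import ExpressionMatrix, PhenotypeTable
from coherence_screen.synthetic_data import SyntheticConfig, generate_expression


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    return ExpressionMatrix(
        gene_ids=["METTL3", "NDUFA10", "GAPDH"],
        sample_ids=["s1", "s2"],
        values=np.array([[9.0, 8.0], [7.5, 6.5], [10.0, 10.1]]),
    )


@pytest.fixture
def random_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    genes = [f"G{i}" for i in range(10)]
    samples = [f"s{i}" for i in range(20)]
    return ExpressionMatrix(genes, samples, rng.normal(8, 1, size=(10, 20)))


@pytest.fixture
def small_synthetic():
    cfg = SyntheticConfig(n_genes=30, n_control=20, n_case=40, seed=7)
    expr, phen, truth = generate_expression(cfg)
    return cfg, expr, phen, truth


@pytest.fixture
def two_group_phenotype() -> PhenotypeTable:
    return PhenotypeTable(
        sample_ids=[f"c{i}" for i in range(5)] + [f"a{i}" for i in range(5)],
        group=["control"] * 5 + ["case"] * 5,
    )
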
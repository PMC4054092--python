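import numpy as np
import pytest

from drugresponse import (
    ExpressionMatrix,
    PhenotypePanel,
    generate_cell_line_panel,
    generate_clinical_cohort,
)


@pytest.fixture
def tiny_expr() -> ExpressionMatrix:
    return ExpressionMatrix(
        gene_ids=["TP53", "EGFR", "KRAS"],
        sample_ids=["s1", "s2"],
        values=np.array([[1.0, 2.0], [3.5, -0.25], [7.125, 0.5]]),
    )


@pytest.fixture
def tiny_pheno() -> PhenotypePanel:
    return PhenotypePanel(
        drug_name="drugX",
        sample_ids=["s1", "s2", "s3", "s4", "s5"],
        ic50=np.array([-1.0, 0.5, np.nan, 2.0, -3.25]),
    )


@pytest.fixture(scope="session")
def small_panel():
    """An 80-line, 300-gene panel with strong signal, shared across tests."""
    return generate_cell_line_panel(
        n_genes=300, n_lines=80, n_causal=20, target_r2=0.7, seed=11
    )


@pytest.fixture(scope="session")
def small_cohort(small_panel):
    _, _, truth = small_panel
    return generate_clinical_cohort(truth, n_patients=30, seed=11)
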
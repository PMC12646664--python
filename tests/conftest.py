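import numpy as np
import pandas as pd
import pytest

from colam import ExpressionCohort, PlantedDesign
from colam.simulate import default_signature_genes, generate_case_control_cohort, parent_signature_for


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_cohort():
    """3 genes x 4 samples, hand-constructed."""
    matrix = pd.DataFrame(
        {
            "S1": [5.0, 1.0, 3.0],
            "S2": [6.0, 2.0, 3.5],
            "S3": [1.0, 5.0, 3.1],
            "S4": [2.0, 6.0, 2.9],
        },
        index=["GENEUP", "GENEDN", "GENEFLAT"],
    )
    ann = pd.DataFrame(
        {"class": ["case", "case", "control", "control"]},
        index=pd.Index(["S1", "S2", "S3", "S4"], name="sample_id"),
    )
    return ExpressionCohort("tiny", matrix, ann)


@pytest.fixture
def planted_world():
    """A comfortable planted cohort (20/20, d=3) with its parent signature."""
    design = PlantedDesign(
        signature_genes=default_signature_genes(15, 15),
        n_background_genes=300,
        effect_size=3.0,
        n_case=20,
        n_control=20,
        seed=11,
    )
    cohort, truth = generate_case_control_cohort(design)
    return design, cohort, truth, parent_signature_for(design)
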
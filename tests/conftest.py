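import numpy as np
import pytest

from vterisk.cohort import Cohort, VariableMeta
from vterisk.simulate import ClinicalGenSpec, VariantSpec, generate_cohort


@pytest.fixture
def tiny_cohort() -> Cohort:
    """4 samples, one SNP (one missing value), one binary, one continuous."""
    schema = [
        VariableMeta("rs1", "genotype", "A"),
        VariableMeta("smoke", "binary"),
        VariableMeta("bmi", "continuous"),
    ]
    values = np.array(
        [
            [0.0, 1.0, 22.0],
            [1.0, 0.0, 27.5],
            [2.0, 0.0, 21.0],
            [np.nan, 1.0, 24.0],
        ]
    )
    return Cohort(["S1", "S2", "S3", "S4"], np.array([1, 1, 0, 0]), schema, values)


@pytest.fixture(scope="session")
def small_signal_cohort():
    """300/300 cohort with one strong SNP, one clinical effect, two decoys."""
    variants = [
        VariantSpec("rs_strong", 0.20, np.log(3.0), "A"),
        VariantSpec("rs_null1", 0.30, 0.0, "C"),
        VariantSpec("rs_null2", 0.45, 0.0, "G"),
    ]
    clinicals = [
        ClinicalGenSpec("expo", "binary", np.log(2.0), prevalence=0.3),
        ClinicalGenSpec("quant", "continuous", 0.0, mean=0.0, sd=1.0, lower=-4, upper=4),
    ]
    cohort, truth = generate_cohort(variants, clinicals, 300, 300, baseline_logit=-2.0, seed=11)
    return cohort, truth
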
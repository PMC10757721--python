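import warnings

import numpy as np
import pytest

from efferotype.datatypes import ExpressionMatrix
from efferotype.synthetic import CohortConfig, generate_cohort

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def default_cohort():
    """One default cohort (n=200, 500 genes, 137 signature genes, effect 1.0)."""
    return generate_cohort(CohortConfig(seed=0))


@pytest.fixture(scope="session")
def log2_expr(default_cohort):
    return ExpressionMatrix(np.log2(default_cohort.expression.values + 1.0), "log2tpm")


@pytest.fixture(scope="session")
def small_cohort():
    """A cheap cohort for pipeline-level tests."""
    return generate_cohort(CohortConfig(n_samples=80, n_genes=160, n_signature_genes=40,
                                        n_lr_pairs=4, seed=11))
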
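import numpy as np
import pytest

from lmsref import CohortConfig, compute_indices, generate_cohort
from lmsref.lms_core import CurveSpec, LMSModel

DOMAIN = (18.0, 82.0)


def make_constant_model(L: float, M: float, S: float, domain=DOMAIN) -> LMSModel:
    """An LMSModel with constant L/M/S curves, for closed-form checks."""
    return LMSModel(
        parameter_name="test",
        sex="male",
        stratum="all",
        L_spec=CurveSpec("constant", 0, domain, (L,)),
        M_spec=CurveSpec("constant", 0, domain, (float(np.log(M)),)),
        S_spec=CurveSpec("constant", 0, domain, (float(np.log(S)),)),
        df=(0, 0, 0),
        domain=domain,
        n_fit=0,
        log_likelihood=0.0,
        bic=0.0,
        converged=True,
        iterations=0,
    )


@pytest.fixture(scope="session")
def small_cohort():
    cohort, curves = generate_cohort(CohortConfig(n_subjects=2000, seed=42))
    return cohort, curves


@pytest.fixture(scope="session")
def indexed_cohort(small_cohort):
    cohort, _ = small_cohort
    return compute_indices(cohort)
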
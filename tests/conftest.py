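import numpy as np
import pytest

from vpop import (
    Cohort,
    VariableSchema,
    fit,
    make_cohort,
    smartool_like,
)


@pytest.fixture(scope="session")
def truth():
    return smartool_like()


@pytest.fixture(scope="session")
def source_cohort(truth):
    """A 186-patient synthetic source cohort, fixed seed."""
    return make_cohort(truth, 186, seed=186)


@pytest.fixture(scope="session")
def source_model(source_cohort):
    return fit(source_cohort)


@pytest.fixture
def toy_cohort():
    """3 patients, one continuous + one binary variable, no missing."""
    schemas = [
        VariableSchema(name="ldl", kind="continuous"),
        VariableSchema(name="smoker", kind="categorical", categories=["No", "Yes"]),
    ]
    values = np.array([[120.0, 2.0], [90.0, 1.0], [150.0, 2.0]])
    return Cohort(
        schemas=schemas,
        values=values,
        mask=np.zeros_like(values, dtype=bool),
        ids=["a", "b", "c"],
    )
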
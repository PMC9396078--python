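import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import opuf

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def eq5d():
    return opuf.eq5d5l()


@pytest.fixture(scope="session")
def toy2x3():
    """Two dimensions with three levels each: 9 states, small enough for
    exhaustive checks."""
    return opuf.DescriptiveSystem(
        dimensions=(
            opuf.Dimension("A", "Alpha", ("none", "some", "lots")),
            opuf.Dimension("B", "Beta", ("none", "some", "lots")),
        ),
        name="toy-2x3",
    )


# A reference respondent used throughout: level ratings (100, 90, 50, 30, 0),
# raw swing weights (100, 60, 40, 80, 70), equal-to-dead state "51255".

REF_RATINGS = (100.0, 90.0, 50.0, 30.0, 0.0)
REF_WEIGHTS = (100.0, 60.0, 40.0, 80.0, 70.0)
REF_DEAD_STATE = "51255"

# The same respondent's coefficient matrix as displayed at two decimals
# (rows = levels best->worst, columns = MO, SC, UA, PD, AD).  Feeding the
# display-rounded cells back in reproduces the printed value chains exactly.
REF_ROUNDED_CELLS = np.array(
    [
        [0.00, 0.00, 0.00, 0.00, 0.00],
        [0.03, 0.02, 0.01, 0.02, 0.02],
        [0.14, 0.09, 0.06, 0.11, 0.10],
        [0.20, 0.12, 0.08, 0.16, 0.14],
        [0.29, 0.17, 0.11, 0.23, 0.20],
    ]
)


@pytest.fixture(scope="session")
def ref_exact_matrix(eq5d):
    """The reference respondent's matrix at full precision."""
    l = opuf.ratings_to_disutilities(REF_RATINGS)
    w = opuf.normalize_weights(REF_WEIGHTS)
    return opuf.build_matrix(l, w, eq5d)


@pytest.fixture(scope="session")
def ref_rounded_matrix(eq5d):
    """The reference respondent's matrix rebuilt from its 2-d.p. display."""
    return opuf.ScaledCoefficientMatrix(REF_ROUNDED_CELLS.copy(), eq5d, atol=0.02)


@pytest.fixture(scope="session")
def population50(eq5d):
    """50 noiseless synthetic respondents and their constructed value sets."""
    sims = opuf.simulate_population(50, seed=1, system=eq5d)
    valuesets = [opuf.construct_valueset(s.record, eq5d) for s in sims]
    return sims, valuesets
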
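import numpy as np
import pytest

from tipstalk.fixtures import REFERENCE_SETS
from tipstalk.steady_state import solve_pattern


@pytest.fixture(scope="session")
def reference_roots():
    """Solve every published parameter set once for its stated spacing.

    Shared across the suite: these roots back the profile-reproduction,
    symmetry, balance and dynamics-agreement tests.
    """
    roots = {}
    for name, case in REFERENCE_SETS.items():
        roots[name] = solve_pattern(case.params, case.spacing)
    return roots


@pytest.fixture()
def rng():
    return np.random.default_rng(20180622)
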
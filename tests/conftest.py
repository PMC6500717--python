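import numpy as np
import pytest

from reintroplan import (
    FixtureSpec,
    ManagementGoal,
    random_life_history,
    validate_stage_matrix,
)

#: 3-stage ungulate life history used throughout the worked examples:
#: stage 1 (juvenile) does not breed; stages 2-3 breed; lambda1 ~ 0.905.
UNGULATE = [[0.0, 0.581, 0.701], [0.141, 0.0, 0.0], [0.0, 0.775, 0.801]]


@pytest.fixture(scope="session")
def ungulate():
    return validate_stage_matrix(UNGULATE)


@pytest.fixture(scope="session")
def ungulate_modified(ungulate):
    """Same life history with stage-3 survival raised to 0.95 (growing)."""
    return ungulate.with_entry(2, 2, 0.95)


@pytest.fixture(scope="session")
def goal():
    """Worked-example goal: 100 breeding females in 7 time units."""
    return ManagementGoal(T=7, B=100)


@pytest.fixture(scope="session")
def random_matrices():
    """100 seeded valid random life histories per stage count m in 2..5."""
    return {
        m: [random_life_history(FixtureSpec(m=m, seed=1000 * m + i))
            for i in range(100)]
        for m in range(2, 6)
    }
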
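import numpy as np
import pandas as pd
import pytest

from loopdep import (
    ExperimentConfig,
    GenerativeParams,
    ResponseMatrix,
    generate_triplets,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def closed_triplets():
    return generate_triplets(60, "between", seed=11, loop_type="closed")


@pytest.fixture(scope="session")
def open_triplets():
    return generate_triplets(60, "between", seed=12, loop_type="open")


@pytest.fixture(scope="session")
def within_triplets():
    return generate_triplets(60, "within", seed=13)


@pytest.fixture(scope="session")
def small_cohort():
    """Six participants, holistic encoding, all-or-none forgetting."""
    params = GenerativeParams(n_participants=6, seed=7)
    return simulate_cohort(params, ExperimentConfig.for_experiment(2))


def make_matrix(responses, loop_types=None, commons=None, participant=1, session="T1"):
    """Hand-build a ResponseMatrix from a (n_events, 6) array of 1/0/-1."""
    responses = np.asarray(responses, dtype=np.int8)
    n = responses.shape[0]
    events = pd.DataFrame(
        {
            "triplet_id": range(n),
            "loop_type": loop_types or ["closed"] * n,
            "common_category": commons or [None] * n,
            "tested_at_T1": [False] * n,
        }
    )
    return ResponseMatrix(participant, session, responses, events)


@pytest.fixture
def perfect_all_or_none():
    """12 closed events: 7 fully correct, 2 fully incorrect, 3 mixed."""
    # the mixed rows disagree on every table's direction pair, so each of the
    # six tables sees exactly n11=7, n00=2, N=12
    rows = [[1] * 6] * 7 + [[0] * 6] * 2
    rows += [[1, 0, 0, 1, 1, 0], [0, 1, 1, 0, 0, 1], [1, 0, 0, 1, 1, 0]]
    return make_matrix(rows)
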
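import copy

import pandas as pd
import pytest
from hypothesis import settings

import quotasim as q
from quotasim.marginals import default_config

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def marginals():
    return q.load_marginals()


@pytest.fixture(scope="session")
def state_counts():
    return dict(q.DEFAULT_STATE_COUNTS)


def degenerate_marginals(trainee_foreign: float = 0.0, ret_mean: float = 62.0):
    """Marginals with every stochastic element collapsed, for oracle checks.

    All male, all full-time, zero retirement-age SD, and an all-Swiss or
    all-foreign trainee pool (``trainee_foreign`` must be 0 or 1).
    """
    assert trainee_foreign in (0.0, 1.0)
    doc = copy.deepcopy(default_config()["survey"])
    doc["gender_counts"] = {"female": 0, "male": 410}
    doc["parttime_counts"] = {"part_time": 0, "full_time": 412}
    doc["retirement_age"] = {
        "male": {"mean": ret_mean, "sd": 0.0},
        "female": {"mean": ret_mean, "sd": 0.0},
    }
    doc["position_by_nationality"]["swiss"]["training"] = int(66 * (1 - trainee_foreign))
    doc["position_by_nationality"]["foreign"]["training"] = int(66 * trainee_foreign)
    return q.SurveyMarginals.from_dict(doc)


ROSTER_DEFAULTS = dict(
    age=40.0, gender="male", nationality="swiss", state="TRANSITION",
    hospital="university", part_time=False, fte_weight=1.0,
    desired_retirement_age=62.0, years_in_state=1.0, total_training_duration=8,
)


def make_roster(rows):
    """Hand-built roster from partial row dicts (defaults filled in)."""
    full = []
    for i, row in enumerate(rows):
        rec = dict(ROSTER_DEFAULTS, person_id=i)
        rec.update(row)
        full.append(rec)
    from quotasim.cohort import ROSTER_COLUMNS

    return pd.DataFrame(full, columns=ROSTER_COLUMNS) if full else pd.DataFrame(
        columns=ROSTER_COLUMNS
    )


@pytest.fixture(scope="session")
def calibrated_run():
    """The full calibrated default projection (hazard grid search + 1000
    replicates), shared across acceptance tests."""
    return q.run_calibrated_pipeline(master_seed=20140522, n_replicates=1000)
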
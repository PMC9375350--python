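import pandas as pd
import pytest
from hypothesis import settings

from carietrack.data_model import CohortFrame

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


def build_cohort(children_rows, obs_rows):
    """Construct a CohortFrame from plain tuples.

    children_rows: (child_id, risk, sex, residence, school_type, att0..att3)
    obs_rows: (child_id, visit, tooth, surface, condition)
    """
    ch = pd.DataFrame(
        children_rows,
        columns=[
            "child_id", "risk", "sex", "residence", "school_type",
            "att0", "att1", "att2", "att3",
        ],
    )
    obs = pd.DataFrame(
        obs_rows, columns=["child_id", "visit", "tooth", "surface", "condition"]
    )
    return CohortFrame(ch, obs)


def child_row(child_id, risk="LOW", att=("ATTENDED",) * 4):
    return (child_id, risk, "MALE", "URBAN", "PUBLIC", *att)


def uniform_child_obs(child_id, visits, condition_by_visit, n_surfaces=10):
    """All-surfaces-same-state observations for one child.

    condition_by_visit maps visit -> either a single condition applied to
    every surface, or a list of per-surface conditions.
    """
    from carietrack.data_model import PERMANENT_TEETH, Surface

    keys = [(t, s.value) for t in PERMANENT_TEETH for s in Surface][:n_surfaces]
    rows = []
    for v in visits:
        cond = condition_by_visit[v]
        conds = [cond] * len(keys) if isinstance(cond, str) else list(cond)
        assert len(conds) == len(keys)
        for (t, s), c in zip(keys, conds):
            rows.append((child_id, v, t, s, c))
    return rows


@pytest.fixture(scope="session")
def default_cohort():
    """One study-sized synthetic cohort, shared across tests."""
    from carietrack.synthetic import default_config, simulate

    cohort, truth = simulate(default_config(seed=11))
    return cohort, truth
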
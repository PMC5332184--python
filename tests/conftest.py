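import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import longmediate as lm

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cc_cohort():
    """Default case-control cohort (482 subjects, visit-level missingness)."""
    return lm.generate_cohort(lm.SimConfig(seed=1))


@pytest.fixture(scope="session")
def full_cohort():
    """A fully observed source cohort (no subsampling, no missingness)."""
    cfg = lm.SimConfig(n_cohort=20_000, sampling=None, missingness_rates=(0.0, 0.0, 0.0), seed=2)
    return lm.generate_cohort(cfg)


def toy_cohort(missing: dict[tuple[int, int], bool] | None = None) -> lm.CohortTable:
    """Tiny hand-built cohort; ``missing`` maps (subject_id, visit) to drop."""
    missing = missing or {}
    subj = pd.DataFrame(
        {
            "subject_id": [1, 2, 3, 4],
            "outcome": [1, 0, 0, 1],
            "weight": [1.0, 2.0, 2.0, 1.0],
            "age": [30.0, 28.0, 35.0, 41.0],
        }
    )
    rows = []
    rng = np.random.default_rng(99)
    for sid in subj["subject_id"]:
        for visit in (1, 2, 3):
            if missing.get((sid, visit)):
                continue
            rows.append(
                {
                    "subject_id": sid,
                    "visit": visit,
                    "exposure": float(np.exp(rng.normal(2.0, 1.0))),
                    "mediator": float(np.exp(rng.normal(3.0, 0.5))),
                    "specific_gravity": float(rng.normal(1.015, 0.005)),
                }
            )
    return lm.CohortTable(subjects=subj, visits=pd.DataFrame(rows))
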
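import numpy as np
import pandas as pd
import pytest

from asmd_sit import (DEFAULT_CATALOG, Cohort, build_sit, default_study_config,
                      generate, merge_hepatosplenomegaly)
from asmd_sit.cohort import GROUPS
from asmd_sit import reference


def cohort_from_counts(symptom_counts=None, group_sizes=None, male_counts=None,
                       ages=None, catalog=DEFAULT_CATALOG):
    """Deterministic cohort with exact per-group symptom margins.

    In each group the first ``count`` patients carry the symptom; columns are
    assigned independently, so all margins are reproduced exactly (the joint
    distribution is arbitrary but fixed).
    """
    symptom_counts = symptom_counts if symptom_counts is not None else reference.SYMPTOM_COUNTS
    group_sizes = group_sizes or reference.GROUP_SIZES
    male_counts = male_counts or reference.MALE_COUNTS
    frames = []
    for g in GROUPS:
        n = group_sizes.get(g, 0)
        if n == 0:
            continue
        data = {
            "patient_id": [f"{g}-{i:05d}" for i in range(n)],
            "group": g,
            "subtype": "none",
            "sex": ["male"] * male_counts.get(g, 0)
                   + ["female"] * (n - male_counts.get(g, 0)),
            "age_onset_years": np.nan,
            "age_current_years": np.nan,
        }
        if ages and g in ages:
            onset, current = ages[g]
            data["age_onset_years"] = onset
            data["age_current_years"] = current
        gi = GROUPS.index(g)
        for sid in catalog.symptom_ids:
            cnt = symptom_counts.get(sid, (0, 0, 0))[gi]
            data[sid] = pd.array([1] * cnt + [0] * (n - cnt), dtype="Int8")
        frames.append(pd.DataFrame(data))
    return Cohort(pd.concat(frames, ignore_index=True), catalog)


@pytest.fixture(scope="session")
def reference_cohort():
    """Cohort reproducing the published per-group symptom counts exactly."""
    return cohort_from_counts()


@pytest.fixture(scope="session")
def study_cohort():
    """The packaged synthetic study fixture (48/52/808, dependence 1, seed 0)."""
    return generate(default_study_config(seed=0))


@pytest.fixture(scope="session")
def merged_study_cohort(study_cohort):
    return merge_hepatosplenomegaly(study_cohort)


@pytest.fixture(scope="session")
def study_sit(merged_study_cohort):
    """Suspicion index fitted on the synthetic study fixture."""
    return build_sit(merged_study_cohort)
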
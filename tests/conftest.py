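from datetime import date, timedelta

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from langtraj.assess import load_bundled_resources
from langtraj.io import validate_cohort

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

INTERVIEW = date(2015, 1, 1)
EVENT = date(2001, 9, 11)


def cohort_rows(sid, day_offsets, pcls, *, age=55.0, gender="male",
                occupation="police", marital="married", interview=INTERVIEW):
    """Rows for one subject; offsets are assessment days relative to interview."""
    return [
        {
            "subject_id": sid,
            "assessment_date": interview + timedelta(days=off),
            "pcl": float(p),
            "interview_date": interview,
            "age_at_interview": age,
            "gender": gender,
            "occupation": occupation,
            "marital_status": marital,
            "event_date": EVENT,
        }
        for off, p in zip(day_offsets, pcls)
    ]


# Hand-built eight-subject cohort exercising every selection rule.
# 365.25 days = 1 year; ±183 days is an exact pre/post |t| tie.
TOY_SUBJECTS = {
    # included everywhere: pre + baseline + 4 posts, last at 3.5 y
    "A": ([-365, 183, 548, 913, 1278], [30, 35, 40, 45, 50]),
    # no pre-interview PCL
    "B": ([183, 365, 1096], [35, 36, 37]),
    # only one PCL, 3 years before the interview: nothing within ±2 y
    "C": ([-1096], [30]),
    # cross-sectional only: 2 post-interview points
    "D": ([-183, 365, 548], [40, 38, 36]),
    # cross-sectional only: 3 posts but last at 1.90 y < 2 y
    "E": ([-183, 183, 365, 694], [40, 42, 44, 46]),
    # boundary: 3 posts with last at 731 d ≈ 2.001 y ≥ 2 y → longitudinal
    "F": ([-183, 183, 365, 731], [50, 48, 46, 44]),
    # baseline tie at ±183 d → pre-interview value (32) wins
    "G": ([-913, -183, 183, 365, 804], [30, 32, 31, 33, 35]),
    # cross-sectional only: no post-interview PCL at all
    "H": ([-548, -183], [25, 28]),
}

TOY_CROSS_SECTIONAL = ["A", "D", "E", "F", "G", "H"]
TOY_LONGITUDINAL = ["A", "F", "G"]
TOY_EXCLUSIONS_LONGITUDINAL = {
    "B": "no_pre_interview_pcl",
    "C": "no_pcl_within_2_years_of_interview",
    "D": "fewer_than_three_post_interview_pcl",
    "E": "last_post_interview_pcl_within_2_years",
    "H": "fewer_than_three_post_interview_pcl",
}
TOY_BASELINES = {"A": 35.0, "D": 40.0, "E": 40.0, "F": 50.0, "G": 32.0, "H": 28.0}


@pytest.fixture(scope="session")
def toy_cohort():
    rows = []
    for sid, (offsets, pcls) in TOY_SUBJECTS.items():
        rows.extend(cohort_rows(sid, offsets, pcls))
    return validate_cohort(pd.DataFrame(rows), source="toy")


@pytest.fixture(scope="session")
def resources():
    """(lexicon, topic model, trait models) shipped with the package."""
    return load_bundled_resources()
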
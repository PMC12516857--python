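"""Shared fixtures: programmatic cohort rows and small hand-built cohorts."""

from __future__ import annotations

import pandas as pd
import pytest

from screenprev.catalog import ENTITY_KEYS, Instrument
from screenprev.cohort import ALL_COLUMNS


def make_row(pid: str, **overrides) -> dict:
    """A valid participant row: heterosexual female, content with her legal
    gender, sub-cohort 2, all screens negative, never interviewed."""
    row = {
        "participant_id": pid,
        "legal_gender": "female",
        "attraction_opposite": "somewhat",
        "attraction_same": "not_at_all",
        "gender_contentment": "happy",
        "sub_cohort": 2,
    }
    for e in ENTITY_KEYS:
        row[f"screen_{e}"] = "negative"
    for i in Instrument:
        row[f"interviewed_{i.value}"] = 0
    for e in ENTITY_KEYS:
        row[f"dx_{e}"] = "unknown"
    row.update(overrides)
    return row


def make_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=ALL_COLUMNS)


@pytest.fixture
def row_factory():
    return make_row


@pytest.fixture
def frame_factory():
    return make_frame


@pytest.fixture
def screened_cohort():
    """20 members, 6 screen-positive for depression, 4 of those interviewed
    (2 diagnosed), 2 screen-positive never reached."""
    rows = []
    for i in range(20):
        over = {}
        if i < 6:
            over["screen_depression"] = "positive"
        if i < 4:
            over["interviewed_mini"] = 1
            over["dx_depression"] = "present" if i < 2 else "absent"
        rows.append(make_row(f"p{i:02d}", **over))
    return make_frame(rows)
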
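"""Individual-level cohort records: domain types, CSV dialect, validation.

The on-disk dialect is deliberately plain: UTF-8, comma-separated, one
header row, missing-value token ``NA``, booleans as 0/1, enums as lowercase
snake-case strings.  One row per participant; per-entity screen and
diagnosis outcomes are wide columns ``screen_<entity>`` / ``dx_<entity>``,
per-instrument interview completion flags ``interviewed_<instrument>``.

Item non-response is kept as missing at ingest and never imputed here;
downstream operations decide exclusion (the per-question denominators of a
survey differ question by question).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .catalog import (
    ENTITY_KEYS,
    Instrument,
    SUBCOHORT_ASYMMETRIC,
    owning_instrument,
)

MISSING = "NA"


class LegalGender(str, Enum):
    FEMALE = "female"
    MALE = "male"


class AttractionLevel(str, Enum):
    NOT_AT_ALL = "not_at_all"
    SOMEWHAT = "somewhat"
    STRONGLY = "strongly"


class ContentmentLevel(str, Enum):
    HAPPY = "happy"
    DOUBTS = "doubts"
    NOT_AT_ALL_COMFORTABLE = "not_at_all_comfortable"


class ScreenResult(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    NOT_SCREENED = "not_screened"


class DiagnosisStatus(str, Enum):
    PRESENT = "present"
    ABSENT = "absent"
    UNKNOWN = "unknown"


@dataclass
class ParticipantRecord:
    """One participant: demographics, identity items, screening, interview
    and diagnosis outcomes."""

    participant_id: str
    legal_gender: LegalGender
    attraction_opposite: AttractionLevel | None
    attraction_same: AttractionLevel | None
    gender_contentment: ContentmentLevel | None
    sub_cohort: int
    screen_result: dict[str, ScreenResult] = field(default_factory=dict)
    interviewed: dict[Instrument, bool] = field(default_factory=dict)
    diagnosis: dict[str, DiagnosisStatus] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# column dialect

ID_COLUMNS = [
    "participant_id",
    "legal_gender",
    "attraction_opposite",
    "attraction_same",
    "gender_contentment",
    "sub_cohort",
]
SCREEN_COLUMNS = [f"screen_{e}" for e in ENTITY_KEYS]
INTERVIEW_COLUMNS = [f"interviewed_{i.value}" for i in Instrument]
DX_COLUMNS = [f"dx_{e}" for e in ENTITY_KEYS]
ALL_COLUMNS = ID_COLUMNS + SCREEN_COLUMNS + INTERVIEW_COLUMNS + DX_COLUMNS

_ENUM_DOMAINS: dict[str, set[str]] = {
    "legal_gender": {g.value for g in LegalGender},
    "attraction_opposite": {a.value for a in AttractionLevel},
    "attraction_same": {a.value for a in AttractionLevel},
    "gender_contentment": {c.value for c in ContentmentLevel},
    **{c: {s.value for s in ScreenResult} for c in SCREEN_COLUMNS},
    **{c: {d.value for d in DiagnosisStatus} for c in DX_COLUMNS},
}
_OPTIONAL_COLUMNS = {"attraction_opposite", "attraction_same", "gender_contentment"}


class CohortValidationError(ValueError):
    """Raised when a cohort file or frame violates the record invariants."""


def _bad_rows(mask: pd.Series) -> list[int]:
    return [int(i) for i in mask[mask].index.tolist()]


def validate_frame(frame: pd.DataFrame) -> None:
    """Check the cohort frame against the record invariants.

    Raises :class:`CohortValidationError` naming the offending column and the
    0-based row indices of every violation.
    """
    missing_cols = [c for c in ALL_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise CohortValidationError(f"missing mandatory columns: {missing_cols}")

    errors: list[str] = []

    if frame["participant_id"].duplicated().any():
        dups = frame["participant_id"][frame["participant_id"].duplicated()]
        errors.append(f"duplicate participant_id values: {sorted(set(dups))[:5]}")

    for col, domain in _ENUM_DOMAINS.items():
        vals = frame[col]
        bad = vals.notna() & ~vals.isin(domain)
        if col not in _OPTIONAL_COLUMNS:
            bad = bad | vals.isna()
        if bad.any():
            errors.append(f"column {col!r}: invalid values in rows {_bad_rows(bad)}")

    bad_sc = ~frame["sub_cohort"].isin([1, 2])
    if bad_sc.any():
        errors.append(f"column 'sub_cohort': must be 1 or 2, rows {_bad_rows(bad_sc)}")

    for col in INTERVIEW_COLUMNS:
        bad = ~frame[col].isin([0, 1, True, False])
        if bad.any():
            errors.append(f"column {col!r}: booleans must be 0/1, rows {_bad_rows(bad)}")

    # diagnosis known only if the owning instrument was interviewed
    for entity in ENTITY_KEYS:
        inst = owning_instrument(entity)
        known = frame[f"dx_{entity}"].isin(["present", "absent"])
        not_interviewed = frame[f"interviewed_{inst.value}"].astype(bool) == False  # noqa: E712
        bad = known & not_interviewed
        if bad.any():
            errors.append(
                f"dx_{entity} recorded without {inst.value} interview in rows {_bad_rows(bad)}"
            )

    # not_screened only for gambling/gaming in sub-cohort 1 without MINI/ADDIS interview
    mini_or_addis = frame["interviewed_mini"].astype(bool) | frame[
        "interviewed_addis"
    ].astype(bool)
    for entity in ENTITY_KEYS:
        ns = frame[f"screen_{entity}"] == "not_screened"
        if entity in SUBCOHORT_ASYMMETRIC:
            bad = ns & ((frame["sub_cohort"] != 1) | mini_or_addis)
        else:
            bad = ns
        if bad.any():
            errors.append(
                f"screen_{entity} = not_screened not allowed in rows {_bad_rows(bad)}"
            )

    if errors:
        raise CohortValidationError("; ".join(errors))


# ---------------------------------------------------------------------------
# frame <-> record conversion

def frame_to_records(frame: pd.DataFrame) -> list[ParticipantRecord]:
    records = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        records.append(
            ParticipantRecord(
                participant_id=str(d["participant_id"]),
                legal_gender=LegalGender(d["legal_gender"]),
                attraction_opposite=(
                    None if pd.isna(d["attraction_opposite"]) else AttractionLevel(d["attraction_opposite"])
                ),
                attraction_same=(
                    None if pd.isna(d["attraction_same"]) else AttractionLevel(d["attraction_same"])
                ),
                gender_contentment=(
                    None if pd.isna(d["gender_contentment"]) else ContentmentLevel(d["gender_contentment"])
                ),
                sub_cohort=int(d["sub_cohort"]),
                screen_result={e: ScreenResult(d[f"screen_{e}"]) for e in ENTITY_KEYS},
                interviewed={i: bool(d[f"interviewed_{i.value}"]) for i in Instrument},
                diagnosis={e: DiagnosisStatus(d[f"dx_{e}"]) for e in ENTITY_KEYS},
            )
        )
    return records


def records_to_frame(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict = {
            "participant_id": r.participant_id,
            "legal_gender": r.legal_gender.value,
            "attraction_opposite": None if r.attraction_opposite is None else r.attraction_opposite.value,
            "attraction_same": None if r.attraction_same is None else r.attraction_same.value,
            "gender_contentment": None if r.gender_contentment is None else r.gender_contentment.value,
            "sub_cohort": r.sub_cohort,
        }
        for e in ENTITY_KEYS:
            row[f"screen_{e}"] = r.screen_result.get(e, ScreenResult.NEGATIVE).value
        for i in Instrument:
            row[f"interviewed_{i.value}"] = int(r.interviewed.get(i, False))
        for e in ENTITY_KEYS:
            row[f"dx_{e}"] = r.diagnosis.get(e, DiagnosisStatus.UNKNOWN).value
        rows.append(row)
    frame = pd.DataFrame(rows, columns=ALL_COLUMNS)
    if frame.empty:
        frame = pd.DataFrame(columns=ALL_COLUMNS)
    return frame


# ---------------------------------------------------------------------------
# I/O

def read_cohort_frame(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV into the canonical frame."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(
        path,
        dtype={"participant_id": str},
        na_values=[MISSING],
        keep_default_na=False,
    )
    validate_frame(frame)
    return frame[ALL_COLUMNS]


def read_cohort(path: str | Path) -> list[ParticipantRecord]:
    """Read a cohort CSV as a list of validated records."""
    return frame_to_records(read_cohort_frame(path))


def write_cohort_frame(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort frame in the canonical dialect (deterministic column
    order, ``NA`` for missing)."""
    validate_frame(frame)
    out = frame[ALL_COLUMNS].copy()
    for c in INTERVIEW_COLUMNS:
        out[c] = out[c].astype(int)
    out.to_csv(path, index=False, na_rep=MISSING, lineterminator="\n")


def write_cohort(records: Sequence[ParticipantRecord], path: str | Path) -> None:
    write_cohort_frame(records_to_frame(records), path)
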
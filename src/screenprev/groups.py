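"""Analysis-group construction from the raw identity items.

Sexual orientation is classified from a two-item attraction measure
(attraction to the opposite sex, attraction to the same sex; each
not-at-all / somewhat / strongly).  Only the at-all vs not-at-all contrast
matters for category membership:

* asexual       — not at all attracted to either sex
* homosexual    — attracted (somewhat or strongly) to same sex only
* heterosexual  — attracted to opposite sex only
* bisexual      — attracted to both
* unclassified  — at least one item missing

Gender discontent (GD) is reporting doubts about, or discomfort with, one's
legal gender.  Orientation analyses are gender-separated and exclude the
unclassified; GD analyses pool legal genders (the GD group is small) and
use everyone who answered the contentment item.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .cohort import AttractionLevel, ContentmentLevel


class OrientationCategory(str, Enum):
    ASEXUAL = "asexual"
    HOMOSEXUAL = "homosexual"
    BISEXUAL = "bisexual"
    HETEROSEXUAL = "heterosexual"
    UNCLASSIFIED = "unclassified"


class GenderDiscontentStatus(str, Enum):
    CONTENT = "content"
    DISCONTENT = "discontent"
    UNKNOWN = "unknown"


ORIENTATION_VALUES = ("asexual", "homosexual", "bisexual", "heterosexual")


def classify_orientation(
    attraction_same: AttractionLevel | str | None,
    attraction_opposite: AttractionLevel | str | None,
) -> OrientationCategory:
    """Orientation category from the two attraction items (total function)."""
    if attraction_same is None or attraction_opposite is None:
        return OrientationCategory.UNCLASSIFIED
    same_at_all = AttractionLevel(attraction_same) is not AttractionLevel.NOT_AT_ALL
    opp_at_all = AttractionLevel(attraction_opposite) is not AttractionLevel.NOT_AT_ALL
    if same_at_all and opp_at_all:
        return OrientationCategory.BISEXUAL
    if same_at_all:
        return OrientationCategory.HOMOSEXUAL
    if opp_at_all:
        return OrientationCategory.HETEROSEXUAL
    return OrientationCategory.ASEXUAL


def classify_gender_discontent(
    contentment: ContentmentLevel | str | None,
) -> GenderDiscontentStatus:
    """GD status: discontent iff doubts or not-at-all-comfortable."""
    if contentment is None:
        return GenderDiscontentStatus.UNKNOWN
    if ContentmentLevel(contentment) is ContentmentLevel.HAPPY:
        return GenderDiscontentStatus.CONTENT
    return GenderDiscontentStatus.DISCONTENT


@dataclass
class AnalysisGroups:
    """Row masks for every analysis group of a cohort frame.

    ``orientation_cells`` maps (legal_gender, orientation) to boolean masks
    over the frame; unclassified records appear in no cell.  ``gd`` /
    ``non_gd`` pool legal genders; ``gd_unknown`` holds item non-response.
    """

    frame: pd.DataFrame
    orientation_cells: dict[tuple[str, str], pd.Series]
    gd: pd.Series
    non_gd: pd.Series
    gd_unknown: pd.Series
    #: per-gender GD masks, populated only when stratify_gd was requested
    gd_by_gender: dict[str, pd.Series] | None = None

    def sizes(self) -> dict[str, int]:
        out = {f"{g}:{o}": int(m.sum()) for (g, o), m in self.orientation_cells.items()}
        out["gd"] = int(self.gd.sum())
        out["non_gd"] = int(self.non_gd.sum())
        out["gd_unknown"] = int(self.gd_unknown.sum())
        return out


def annotate(frame: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the frame with derived ``orientation`` and
    ``gd_status`` columns."""
    out = frame.copy()
    out["orientation"] = [
        classify_orientation(
            None if pd.isna(s) else s, None if pd.isna(o) else o
        ).value
        for s, o in zip(frame["attraction_same"], frame["attraction_opposite"])
    ]
    out["gd_status"] = [
        classify_gender_discontent(None if pd.isna(c) else c).value
        for c in frame["gender_contentment"]
    ]
    return out


def build_analysis_groups(frame: pd.DataFrame, stratify_gd: bool = False) -> AnalysisGroups:
    """Assign every record to at most one orientation × legal-gender cell and
    exactly one of GD / non-GD / unknown.

    ``stratify_gd`` additionally exposes per-gender GD masks; the default
    pools legal genders, the reporting convention for a group this small.
    """
    ann = annotate(frame)
    cells: dict[tuple[str, str], pd.Series] = {}
    for gender in ("female", "male"):
        for orient in ORIENTATION_VALUES:
            cells[(gender, orient)] = (ann["legal_gender"] == gender) & (
                ann["orientation"] == orient
            )
    gd = ann["gd_status"] == "discontent"
    non_gd = ann["gd_status"] == "content"
    unknown = ann["gd_status"] == "unknown"
    by_gender = None
    if stratify_gd:
        by_gender = {
            g: gd & (ann["legal_gender"] == g) for g in ("female", "male")
        }
    return AnalysisGroups(
        frame=frame, orientation_cells=cells, gd=gd, non_gd=non_gd,
        gd_unknown=unknown, gd_by_gender=by_gender,
    )
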
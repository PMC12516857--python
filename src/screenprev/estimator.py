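"""Two-phase adjusted prevalence estimation.

A cheap, high-sensitivity screen (Phase 1) selects participants for a
diagnostic interview (Phase 2).  Within a group of total size ``T`` and a
diagnostic entity, let

* ``D``  — interviewed with the diagnosis,
* ``ND`` — interviewed (on the owning instrument) without it,
* ``NI`` — screen-positive but not interviewed.

Screen-negatives are assumed free of the diagnosis; non-interviewed
screen-positives are assumed to have the same prevalence as interviewed
ones (missing at random given screen status).  The adjusted prevalence is

    P = (D + (D / (D + ND)) * NI) / T

For entities whose Phase-1 screen was administered to only one of the two
school sub-cohorts via the questionnaire (gambling and gaming), sub-cohort-1
members never screened (``NS1``) are imputed at the adjusted prevalence
``PD2`` observed among sub-cohort-2 members not reached through the other
interviews:

    P = (D + (D / (D + ND)) * NI + PD2 * NS1) / T
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

import pandas as pd

from .catalog import (
    COMPOSITES,
    ENTITY_BY_KEY,
    ENTITY_KEYS,
    SUBCOHORT_ASYMMETRIC,
    owning_instrument,
)


class InestimableCellError(ValueError):
    """Screen-positives lost to follow-up with no interviewed screen-positive
    to anchor the adjustment (NI > 0 while D + ND = 0)."""


class EmptyReferenceSubcohortError(InestimableCellError):
    """No sub-cohort-2 member outside the M.I.N.I./ADDIS interviews to supply
    the gambling/gaming reference prevalence PD2."""


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding (display convention; banker's rounding would
    disagree on exact .5 ties)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TwoPhaseCounts:
    """Aggregate counts feeding the prevalence formula."""

    D: int
    ND: int
    NI: int
    T: int
    PD2: float | None = None
    NS1: int | None = None

    def __post_init__(self) -> None:
        for name in ("D", "ND", "NI", "T"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if (self.PD2 is None) != (self.NS1 is None):
            raise ValueError("PD2 and NS1 must be provided together")
        if self.NS1 is not None and (self.NS1 < 0 or int(self.NS1) != self.NS1):
            raise ValueError(f"NS1 must be a non-negative integer, got {self.NS1!r}")
        if self.PD2 is not None and not 0.0 <= self.PD2 <= 1.0:
            raise ValueError(f"PD2 must be a proportion, got {self.PD2!r}")
        ns1 = self.NS1 or 0
        if self.D + self.ND + self.NI + ns1 > self.T:
            raise ValueError("D + ND + NI + NS1 exceeds group size T")


@dataclass(frozen=True)
class PrevalenceEstimate:
    group: str
    entity: str
    P: float
    counts: TwoPhaseCounts

    @property
    def percent_1dp(self) -> float:
        return round_half_up(self.P * 100.0, 1)


def estimate_prevalence(
    counts: TwoPhaseCounts, group: str = "", entity: str = ""
) -> PrevalenceEstimate:
    """Apply the adjustment formula to a set of two-phase counts."""
    if counts.T <= 0:
        raise ValueError("group size T must be positive")
    if counts.NI > 0 and counts.D + counts.ND == 0:
        raise InestimableCellError(
            f"group={group!r} entity={entity!r}: {counts.NI} screen-positive "
            "non-interviewed but no interviewed screen-positive to estimate from"
        )
    if counts.D + counts.ND > 0:
        adjusted = counts.D + counts.D / (counts.D + counts.ND) * counts.NI
    else:
        adjusted = float(counts.D)
    if counts.PD2 is not None and counts.NS1 is not None:
        adjusted += counts.PD2 * counts.NS1
    return PrevalenceEstimate(group=group, entity=entity, P=adjusted / counts.T, counts=counts)


# ---------------------------------------------------------------------------
# aggregation from cohort frames

def _basic_counts(sub: pd.DataFrame, entity: str) -> tuple[int, int, int]:
    inst = owning_instrument(entity)
    dx = sub[f"dx_{entity}"]
    interviewed = sub[f"interviewed_{inst.value}"].astype(bool)
    d = int((dx == "present").sum())
    nd = int(((dx == "absent") & interviewed).sum())
    ni = int(((sub[f"screen_{entity}"] == "positive") & ~interviewed).sum())
    return d, nd, ni


def compute_pd2(sub: pd.DataFrame, entity: str) -> float:
    """Reference prevalence of a gambling/gaming entity among sub-cohort-2
    members not interviewed with M.I.N.I. or ADDIS (all of whom carried the
    questionnaire screen).  Itself attrition-adjusted."""
    if entity not in SUBCOHORT_ASYMMETRIC:
        raise ValueError(f"PD2 defined only for {sorted(SUBCOHORT_ASYMMETRIC)}, got {entity!r}")
    mini_or_addis = sub["interviewed_mini"].astype(bool) | sub["interviewed_addis"].astype(bool)
    ref = sub[(sub["sub_cohort"] == 2) & ~mini_or_addis]
    if len(ref) == 0:
        raise EmptyReferenceSubcohortError(
            f"reference sub-cohort empty for entity {entity!r}"
        )
    d, nd, ni = _basic_counts(ref, entity)
    est = estimate_prevalence(
        TwoPhaseCounts(D=d, ND=nd, NI=ni, T=len(ref)), group="pd2_reference", entity=entity
    )
    return est.P


def aggregate_counts(sub: pd.DataFrame, entity: str) -> TwoPhaseCounts:
    """Two-phase counts for one analysis group (a row-subset frame) and one
    catalog entity.  For sub-cohort-asymmetric entities the never-screened
    cohort-1 members enter NS1 with PD2 computed within the same group."""
    if entity not in ENTITY_BY_KEY:
        raise KeyError(f"unknown diagnosis entity: {entity!r}")
    d, nd, ni = _basic_counts(sub, entity)
    pd2: float | None = None
    ns1: int | None = None
    if entity in SUBCOHORT_ASYMMETRIC:
        n_never = int(
            ((sub["sub_cohort"] == 1) & (sub[f"screen_{entity}"] == "not_screened")).sum()
        )
        if n_never > 0:
            ns1 = n_never
            pd2 = compute_pd2(sub, entity)
    return TwoPhaseCounts(D=d, ND=nd, NI=ni, T=len(sub), PD2=pd2, NS1=ns1)


def estimate_entity(sub: pd.DataFrame, entity: str, group: str = "") -> PrevalenceEstimate:
    return estimate_prevalence(aggregate_counts(sub, entity), group=group, entity=entity)


def estimate_composite(
    sub: pd.DataFrame, members: Iterable[str], group: str = "", label: str = ""
) -> PrevalenceEstimate:
    """Person-level any-of union over a member set of entities.

    D: persons with at least one member diagnosis present.
    ND: persons interviewed on every member entity their screens indicated,
        with no member diagnosis.
    NI: screen-positive persons with no recorded member diagnosis and at
        least one indicated-but-missing interview.
    Persons with no screening indication for any member contribute only to T.
    """
    members = list(members)
    unknown = [m for m in members if m not in ENTITY_BY_KEY]
    if unknown:
        raise KeyError(f"unknown diagnosis entities: {unknown}")
    any_present = pd.Series(False, index=sub.index)
    any_indicated = pd.Series(False, index=sub.index)
    any_missing = pd.Series(False, index=sub.index)  # indicated but not followed up
    for m in members:
        indicated = sub[f"screen_{m}"] == "positive"
        any_present |= sub[f"dx_{m}"] == "present"
        any_indicated |= indicated
        any_missing |= indicated & (sub[f"dx_{m}"] == "unknown")
    d = int(any_present.sum())
    nd = int((any_indicated & ~any_present & ~any_missing).sum())
    ni = int((~any_present & any_missing).sum())
    counts = TwoPhaseCounts(D=d, ND=nd, NI=ni, T=len(sub))
    return estimate_prevalence(counts, group=group, entity=label or "+".join(members))


def mean_diagnosis_count(sub: pd.DataFrame, group: str = "") -> float:
    """Expected number of the 20 diagnoses per group member: the sum of the
    20 adjusted prevalences, so the attrition adjustment is inherited."""
    if len(sub) == 0:
        raise ValueError("group is empty")
    return float(sum(estimate_entity(sub, e, group=group).P for e in ENTITY_KEYS))


def composite_members(name: str) -> tuple[str, ...]:
    try:
        return COMPOSITES[name]
    except KeyError:
        raise KeyError(f"unknown composite: {name!r}") from None
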
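"""Two-phase adjusted prevalence: formula arithmetic, aggregation from
records, composites and the mean-diagnosis identity."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from screenprev import (
    InestimableCellError,
    TwoPhaseCounts,
    aggregate_counts,
    compute_pd2,
    estimate_composite,
    estimate_entity,
    estimate_prevalence,
    mean_diagnosis_count,
)
from screenprev.estimator import EmptyReferenceSubcohortError, round_half_up

from conftest import make_frame, make_row


def direct_formula(D, ND, NI, T, PD2=0.0, NS1=0):
    """Independent oracle: literal evaluation of the published formula."""
    return (D + (D / (D + ND)) * NI + PD2 * NS1) / T if D + ND else (D + PD2 * NS1) / T


@pytest.mark.parametrize(
    "counts, expected",
    [
        (TwoPhaseCounts(D=0, ND=10, NI=5, T=100), 0.0),
        (TwoPhaseCounts(D=4, ND=6, NI=0, T=50), 0.08),
        (TwoPhaseCounts(D=5, ND=15, NI=8, T=200), 0.035),
        (TwoPhaseCounts(D=2, ND=8, NI=5, PD2=0.1, NS1=40, T=400), 0.0175),
    ],
)
def test_worked_arithmetic_cases(counts, expected):
    est = estimate_prevalence(counts)
    assert est.P == pytest.approx(expected, abs=1e-12)
    assert est.P == pytest.approx(
        direct_formula(counts.D, counts.ND, counts.NI, counts.T,
                       counts.PD2 or 0.0, counts.NS1 or 0),
        abs=1e-12,
    )


def test_extended_formula_reduces_to_basic():
    basic = estimate_prevalence(TwoPhaseCounts(D=3, ND=9, NI=4, T=60)).P
    with_zero_ns1 = estimate_prevalence(
        TwoPhaseCounts(D=3, ND=9, NI=4, T=60, PD2=0.37, NS1=0)
    ).P
    with_zero_pd2 = estimate_prevalence(
        TwoPhaseCounts(D=3, ND=9, NI=4, T=60, PD2=0.0, NS1=20)
    ).P
    assert basic == with_zero_ns1 == with_zero_pd2


def test_inestimable_cell_raises_not_zero():
    with pytest.raises(InestimableCellError):
        estimate_prevalence(TwoPhaseCounts(D=0, ND=0, NI=3, T=10))
    with pytest.raises(ValueError, match="T must be positive"):
        estimate_prevalence(TwoPhaseCounts(D=0, ND=0, NI=0, T=0))


def test_counts_invariants_enforced():
    with pytest.raises(ValueError):
        TwoPhaseCounts(D=-1, ND=0, NI=0, T=5)
    with pytest.raises(ValueError, match="together"):
        TwoPhaseCounts(D=0, ND=0, NI=0, T=5, PD2=0.1)
    with pytest.raises(ValueError, match="exceeds"):
        TwoPhaseCounts(D=4, ND=4, NI=4, T=10)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    d=st.integers(0, 30),
    nd=st.integers(0, 30),
    ni=st.integers(0, 30),
    extra=st.integers(0, 50),
)
def test_bounds_and_monotonicity(d, nd, ni, extra):
    """D/T <= P <= (D+NI)/T; P non-decreasing in D and (for D>0) in NI."""
    t = d + nd + ni + extra + 2
    if ni > 0 and d + nd == 0:
        with pytest.raises(InestimableCellError):
            estimate_prevalence(TwoPhaseCounts(D=d, ND=nd, NI=ni, T=t))
        return
    p = estimate_prevalence(TwoPhaseCounts(D=d, ND=nd, NI=ni, T=t)).P
    assert d / t - 1e-12 <= p <= (d + ni) / t + 1e-12
    p_more_d = estimate_prevalence(TwoPhaseCounts(D=d + 1, ND=nd, NI=ni, T=t)).P
    assert p_more_d >= p - 1e-12
    if d > 0:
        p_more_ni = estimate_prevalence(TwoPhaseCounts(D=d, ND=nd, NI=ni + 1, T=t)).P
        assert p_more_ni >= p - 1e-12


def test_aggregate_counts_hand_fixture(screened_cohort):
    counts = aggregate_counts(screened_cohort, "depression")
    assert (counts.D, counts.ND, counts.NI, counts.T) == (2, 2, 2, 20)
    est = estimate_entity(screened_cohort, "depression")
    assert est.P == pytest.approx((2 + 0.5 * 2) / 20, abs=1e-12)


def test_aggregate_counts_no_screen_positives(frame_factory, row_factory):
    frame = make_frame([make_row(f"p{i}") for i in range(10)])
    counts = aggregate_counts(frame, "depression")
    assert (counts.D, counts.ND, counts.NI, counts.T) == (0, 0, 0, 10)
    assert estimate_entity(frame, "depression").P == 0.0
    with pytest.raises(KeyError, match="unknown diagnosis entity"):
        aggregate_counts(frame, "melancholia")


def _gambling_mixed_cohort():
    """5 never-screened sub-cohort-1 members; sub-cohort-2 reference subset
    of 50 with 5 screen-positive all interviewed, 2 diagnosed."""
    rows = []
    for i in range(5):  # sub-cohort 1, never reached for MINI/ADDIS
        rows.append(make_row(f"s1_{i}", sub_cohort=1, screen_gambling="not_screened"))
    for i in range(50):  # sub-cohort 2, questionnaire-screened
        over = {}
        if i < 5:
            over = {"screen_gambling": "positive", "interviewed_nods": 1,
                    "dx_gambling": "present" if i < 2 else "absent"}
        rows.append(make_row(f"s2_{i}", sub_cohort=2, **over))
    return make_frame(rows)


def test_gambling_aggregation_attaches_pd2():
    frame = _gambling_mixed_cohort()
    counts = aggregate_counts(frame, "gambling")
    assert counts.NS1 == 5
    assert counts.PD2 == pytest.approx(2 / 50, abs=1e-12)
    assert (counts.D, counts.ND, counts.NI, counts.T) == (2, 3, 0, 55)
    est = estimate_prevalence(counts)
    assert est.P == pytest.approx((2 + 0.04 * 5) / 55, abs=1e-12)


def test_compute_pd2_worked_cases():
    # all screen-negative reference subset -> 0
    frame = make_frame([make_row(f"p{i}", sub_cohort=2) for i in range(30)])
    assert compute_pd2(frame, "gambling") == 0.0
    # subset of 50 with D=2, ND=2, NI=4 -> (2 + 1*4... wait, D/(D+ND)=0.5) -> (2+2)/50
    rows = []
    for i in range(50):
        over = {}
        if i < 4:
            over = {"screen_gambling": "positive", "interviewed_nods": 1,
                    "dx_gambling": "present" if i < 2 else "absent"}
        elif i < 8:
            over = {"screen_gambling": "positive"}
        rows.append(make_row(f"p{i}", sub_cohort=2, **over))
    assert compute_pd2(make_frame(rows), "gambling") == pytest.approx(0.08, abs=1e-12)
    with pytest.raises(ValueError, match="PD2 defined only"):
        compute_pd2(frame, "depression")
    empty = make_frame([make_row("p0", sub_cohort=1, screen_gambling="not_screened")])
    with pytest.raises(EmptyReferenceSubcohortError, match="reference sub-cohort empty"):
        compute_pd2(empty, "gambling")


def test_composite_singleton_equals_entity(screened_cohort):
    single = estimate_composite(screened_cohort, ["depression"])
    entity = estimate_entity(screened_cohort, "depression")
    assert single.P == pytest.approx(entity.P, abs=1e-12)
    assert (single.counts.D, single.counts.ND, single.counts.NI) == (
        entity.counts.D, entity.counts.ND, entity.counts.NI)


def test_composite_counts_multimorbid_person_once():
    rows = [
        make_row("p0", screen_depression="positive", screen_suicidality="positive",
                 interviewed_mini=1, dx_depression="present", dx_suicidality="present"),
        make_row("p1"),
        make_row("p2"),
        make_row("p3"),
    ]
    est = estimate_composite(make_frame(rows), ["depression", "suicidality"])
    assert est.counts.D == 1
    assert est.P == pytest.approx(0.25, abs=1e-12)


def test_composite_d_sums_when_diagnoses_disjoint():
    """With one diagnosis per person and all indicated interviews complete,
    composite D equals the sum of member D's."""
    rows = []
    for i, e in enumerate(["depression", "suicidality", "ocd"]):
        rows.append(make_row(f"p{i}", **{f"screen_{e}": "positive",
                                         "interviewed_mini": 1, f"dx_{e}": "present"}))
    rows += [make_row(f"q{i}") for i in range(7)]
    frame = make_frame(rows)
    members = ["depression", "suicidality", "ocd"]
    comp = estimate_composite(frame, members)
    assert comp.counts.D == sum(aggregate_counts(frame, e).D for e in members) == 3
    assert comp.P == pytest.approx(0.3, abs=1e-12)


def test_composite_ni_needs_missing_indicated_interview():
    rows = [
        make_row("p0", screen_depression="positive"),  # indicated, never interviewed
        make_row("p1", screen_depression="positive", interviewed_mini=1,
                 dx_depression="absent"),
        make_row("p2"),
    ]
    comp = estimate_composite(make_frame(rows), ["depression", "suicidality"])
    assert (comp.counts.D, comp.counts.ND, comp.counts.NI) == (0, 1, 1)


def test_mean_diagnosis_count_identity():
    # 5 persons, diagnoses {2,1,0,0,1} spread over entities, full follow-up
    rows = [
        make_row("p0", screen_depression="positive", screen_suicidality="positive",
                 interviewed_mini=1, dx_depression="present", dx_suicidality="present"),
        make_row("p1", screen_ocd="positive", interviewed_mini=1, dx_ocd="present"),
        make_row("p2"),
        make_row("p3"),
        make_row("p4", screen_alcohol="positive", interviewed_addis=1,
                 dx_alcohol="present"),
    ]
    frame = make_frame(rows)
    assert mean_diagnosis_count(frame) == pytest.approx(0.80, abs=1e-12)
    zero = make_frame([make_row("a"), make_row("b")])
    assert mean_diagnosis_count(zero) == 0.0
    with pytest.raises(ValueError, match="empty"):
        mean_diagnosis_count(frame.iloc[0:0])


def test_rounding_convention_is_half_up():
    assert round_half_up(0.125, 2) == 0.13
    assert round_half_up(2.5, 0) == 3.0
    assert round_half_up(13.85, 1) == 13.9
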
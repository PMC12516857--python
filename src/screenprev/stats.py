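"""Relative risks and chi-square significance with star coding.

RR is the prevalence in a minority group divided by the prevalence in its
reference group (same-gender heterosexuals for orientation cells; all
others for the gender-discontent group), defined only when both prevalences
are positive.  Differences are tested with a Pearson chi-square on the 2x2
table of estimated case / non-case counts, without continuity correction;
tables with any expected cell below 5 are flagged.  No multiple-testing
correction is applied anywhere in this module: every p-value is marginal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .estimator import PrevalenceEstimate, round_half_up

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars(p: float) -> str:
    """Significance stars: *** p<0.001, ** p<0.01, * p<0.05, else 'ns'."""
    for cut, code in STAR_THRESHOLDS:
        if p < cut:
            return code
    return "ns"


def relative_risk(p_group: float, p_ref: float) -> float | None:
    """p_group / p_ref when both are positive; None (rendered '-') otherwise."""
    for name, v in (("p_group", p_group), ("p_ref", p_ref)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be a proportion, got {v!r}")
    if p_group > 0.0 and p_ref > 0.0:
        return p_group / p_ref
    return None


def chi_square_test(
    cases_a: int, noncases_a: int, cases_b: int, noncases_b: int
) -> tuple[float, float, bool]:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table.

    Returns ``(chi2, p, small_expected)`` where ``small_expected`` flags any
    expected cell below 5.  A margin that is zero in both groups (all cases
    or all non-cases) is a degenerate table: chi2 = 0, p = 1.
    """
    table = np.array([[cases_a, noncases_a], [cases_b, noncases_b]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if table[0].sum() == 0 or table[1].sum() == 0:
        raise ValueError("both group totals must be positive")
    if table.sum(axis=0).min() == 0:
        return 0.0, 1.0, True
    res = sps.chi2_contingency(table, correction=False)
    small = bool((res.expected_freq < 5).any())
    return float(res.statistic), float(res.pvalue), small


@dataclass(frozen=True)
class GroupComparison:
    group: str
    reference: str
    entity: str
    RR: float | None
    chi2: float
    p: float
    stars: str
    small_expected: bool

    @property
    def rr_2dp(self) -> str:
        return "-" if self.RR is None else f"{round_half_up(self.RR, 2):.2f}"


def compare_estimates(
    est: PrevalenceEstimate, ref: PrevalenceEstimate
) -> GroupComparison:
    """RR and chi-square comparison of one group estimate against its
    reference.  The 2x2 table uses adjusted case counts rounded to the
    nearest integer (P*T), vs the complementary non-case counts."""
    rr = relative_risk(est.P, ref.P)
    ca = int(round_half_up(est.P * est.counts.T, 0))
    cb = int(round_half_up(ref.P * ref.counts.T, 0))
    chi2, p, small = chi_square_test(
        ca, est.counts.T - ca, cb, ref.counts.T - cb
    )
    return GroupComparison(
        group=est.group,
        reference=ref.group,
        entity=est.entity,
        RR=rr,
        chi2=chi2,
        p=p,
        stars=stars(p),
        small_expected=small,
    )


def compare_groups(
    estimates: dict[str, PrevalenceEstimate], scheme: dict[str, str]
) -> list[GroupComparison]:
    """Compare groups per a {group_label: reference_label} scheme for a single
    entity's estimates keyed by group label."""
    out = []
    for group, reference in scheme.items():
        if group not in estimates:
            continue
        if reference not in estimates:
            raise KeyError(f"missing reference group {reference!r} for {group!r}")
        out.append(compare_estimates(estimates[group], estimates[reference]))
    return out
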
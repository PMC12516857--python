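"""End-to-end pipeline orchestration and table rendering.

``run_pipeline`` takes a validated cohort frame and produces an
:class:`AnalysisReport`: adjusted prevalence for every analysis group and
diagnostic entity, the two composite outcomes, mean diagnosis counts,
relative risks against the design's reference groups with chi-square star
coding, and the list of all-zero group columns dropped from display.

Cells where the adjustment is undefined (screen-positives lost to follow-up
with no interviewed screen-positive) are recorded as inestimable — P is NaN
and the cell is listed loudly — rather than silently zeroed, which would
bias low.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import COMPOSITES, ENTITY_BY_KEY, ENTITY_KEYS
from .estimator import (
    InestimableCellError,
    PrevalenceEstimate,
    estimate_composite,
    estimate_entity,
    round_half_up,
)
from .groups import build_analysis_groups
from .stats import GroupComparison, compare_estimates

logger = logging.getLogger(__name__)

#: display order of analysis-group columns
GROUP_ORDER = [
    "female:asexual",
    "female:homosexual",
    "female:bisexual",
    "female:heterosexual",
    "male:asexual",
    "male:homosexual",
    "male:bisexual",
    "male:heterosexual",
    "gd",
    "non_gd",
]
#: reference group per compared (minority) group
COMPARISON_SCHEME = {
    "female:asexual": "female:heterosexual",
    "female:homosexual": "female:heterosexual",
    "female:bisexual": "female:heterosexual",
    "male:asexual": "male:heterosexual",
    "male:homosexual": "male:heterosexual",
    "male:bisexual": "male:heterosexual",
    "gd": "non_gd",
}

ROW_ORDER = list(ENTITY_KEYS) + list(COMPOSITES)

ROW_LABELS = {**{e: ENTITY_BY_KEY[e].label for e in ENTITY_KEYS},
              "any_anxiety": "Any anxiety disorder",
              "at_least_one": "At least one of all 20 diagnoses above"}


@dataclass
class AnalysisReport:
    group_sizes: dict[str, int]
    estimates: dict[tuple[str, str], PrevalenceEstimate]
    comparisons: dict[tuple[str, str], GroupComparison]
    mean_diagnoses: dict[str, float]
    inestimable: list[tuple[str, str]] = field(default_factory=list)
    dropped_columns: list[str] = field(default_factory=list)

    def estimates_frame(self) -> pd.DataFrame:
        """Long-format results: group, entity, counts, P, percent."""
        rows = []
        for (group, entity), est in self.estimates.items():
            c = est.counts
            rows.append(
                {
                    "group": group,
                    "entity": entity,
                    "D": c.D,
                    "ND": c.ND,
                    "NI": c.NI,
                    "NS1": c.NS1,
                    "PD2": c.PD2,
                    "T": c.T,
                    "P": est.P,
                    "percent_1dp": est.percent_1dp,
                }
            )
        return pd.DataFrame(rows)

    def comparisons_frame(self) -> pd.DataFrame:
        rows = []
        for (group, entity), comp in self.comparisons.items():
            rows.append(
                {
                    "group": group,
                    "reference": comp.reference,
                    "entity": entity,
                    "RR": comp.rr_2dp,
                    "chi2": comp.chi2,
                    "p": comp.p,
                    "stars": comp.stars,
                    "small_expected": comp.small_expected,
                }
            )
        return pd.DataFrame(rows)


def run_pipeline(
    cohort: pd.DataFrame, drop_zero_columns: bool = True
) -> AnalysisReport:
    """Read-validate-group-estimate-compare, mirroring the study's
    participant-flow accounting in the log."""
    groups = build_analysis_groups(cohort)

    screen_cols = [f"screen_{e}" for e in ENTITY_KEYS]
    any_selected = (cohort[screen_cols] == "positive").any(axis=1)
    any_interviewed = (
        cohort[[c for c in cohort.columns if c.startswith("interviewed_")]]
        .astype(bool)
        .any(axis=1)
    )
    logger.info(
        "cohort N=%d; selected by screening n=%d; interviewed n=%d (%.1f%% of selected)",
        len(cohort),
        int(any_selected.sum()),
        int(any_interviewed.sum()),
        100.0 * any_interviewed.sum() / max(int(any_selected.sum()), 1),
    )

    masks: dict[str, pd.Series] = {
        f"{g}:{o}": m for (g, o), m in groups.orientation_cells.items()
    }
    masks["gd"] = groups.gd
    masks["non_gd"] = groups.non_gd

    estimates: dict[tuple[str, str], PrevalenceEstimate] = {}
    inestimable: list[tuple[str, str]] = []
    mean_diag: dict[str, float] = {}
    for label in GROUP_ORDER:
        sub = cohort[masks[label]]
        if len(sub) == 0:
            continue
        total = 0.0
        any_nan = False
        for entity in ENTITY_KEYS:
            try:
                est = estimate_entity(sub, entity, group=label)
            except InestimableCellError:
                inestimable.append((label, entity))
                est = PrevalenceEstimate(group=label, entity=entity, P=float("nan"),
                                         counts=_nan_counts(sub, entity))
                any_nan = True
            estimates[(label, entity)] = est
            total += est.P
        for comp_name, members in COMPOSITES.items():
            try:
                est = estimate_composite(sub, members, group=label, label=comp_name)
            except InestimableCellError:
                inestimable.append((label, comp_name))
                est = PrevalenceEstimate(group=label, entity=comp_name, P=float("nan"),
                                         counts=_nan_counts(sub, None))
            estimates[(label, comp_name)] = est
        mean_diag[label] = float("nan") if any_nan else total

    comparisons: dict[tuple[str, str], GroupComparison] = {}
    for group, refg in COMPARISON_SCHEME.items():
        for entity in ROW_ORDER:
            est = estimates.get((group, entity))
            ref = estimates.get((refg, entity))
            if est is None or ref is None:
                continue
            if np.isnan(est.P) or np.isnan(ref.P):
                continue
            comparisons[(group, entity)] = compare_estimates(est, ref)

    dropped: list[str] = []
    if drop_zero_columns:
        for label in GROUP_ORDER:
            ests = [estimates.get((label, e)) for e in ENTITY_KEYS]
            ests = [e for e in ests if e is not None]
            if ests and all((not np.isnan(e.P)) and e.P == 0.0 for e in ests):
                dropped.append(label)
                logger.info("dropping all-zero group column %s", label)

    return AnalysisReport(
        group_sizes={k: int(m.sum()) for k, m in masks.items()},
        estimates=estimates,
        comparisons=comparisons,
        mean_diagnoses=mean_diag,
        inestimable=inestimable,
        dropped_columns=dropped,
    )


def _nan_counts(sub, entity):
    from .estimator import TwoPhaseCounts

    return TwoPhaseCounts(D=0, ND=0, NI=0, T=max(len(sub), 1))


# ---------------------------------------------------------------------------
# rendering

def _fmt_pct(est: PrevalenceEstimate | None, stars: str | None) -> str:
    if est is None:
        return ""
    if np.isnan(est.P):
        return "inestimable"
    s = "0" if est.P == 0 else f"{est.percent_1dp:.1f}"
    if stars and stars != "ns":
        s += stars
    elif stars == "ns" and est.P > 0:
        s += " n.s."
    return s


def report_table(report: AnalysisReport) -> pd.DataFrame:
    """Wide display table: one row per entity/composite plus the mean-count
    row; per compared group a percent column (star-suffixed) and an RR
    column; per reference group a percent column."""
    columns = [g for g in GROUP_ORDER if g not in report.dropped_columns
               and g in report.group_sizes and report.group_sizes[g] > 0]
    data: dict[str, list[str]] = {}
    for g in columns:
        pct_col, rr_col = [], []
        for row in ROW_ORDER:
            est = report.estimates.get((g, row))
            comp = report.comparisons.get((g, row))
            pct_col.append(_fmt_pct(est, comp.stars if comp else None))
            if g in COMPARISON_SCHEME:
                rr_col.append("" if comp is None else comp.rr_2dp)
        m = report.mean_diagnoses.get(g, float("nan"))
        pct_col.append("" if np.isnan(m) else f"{round_half_up(m, 2):.2f}")
        header = f"{g} (n={report.group_sizes[g]})"
        data[f"{header} %"] = pct_col
        if g in COMPARISON_SCHEME:
            rr_col.append("")
            data[f"{header} RR"] = rr_col
    index = [ROW_LABELS[r] for r in ROW_ORDER] + ["No. of diagnoses (mean)"]
    return pd.DataFrame(data, index=index)


def render_table(report: AnalysisReport, format: str = "text") -> str:
    """Render the report deterministically as csv, markdown or text."""
    table = report_table(report)
    if format == "csv":
        buf = io.StringIO()
        table.to_csv(buf, index_label="Diagnostic entity", lineterminator="\n")
        return buf.getvalue()
    if format == "markdown":
        header = ["Diagnostic entity", *table.columns]
        lines = ["| " + " | ".join(header) + " |",
                 "| " + " | ".join("---" for _ in header) + " |"]
        for idx, row in table.iterrows():
            lines.append("| " + " | ".join([str(idx), *map(str, row)]) + " |")
        return "\n".join(lines) + "\n"
    if format == "text":
        legend = "Significance: * p<0.05; ** p<0.01; *** p<0.001 (uncorrected)\n"
        return table.to_string() + "\n" + legend
    raise ValueError(f"unknown format {format!r}")


def replicate_printed_rrs(
    pairs: list[tuple[float, float]]
) -> list[float | None]:
    """RRs recomputed from rounded published prevalence percentages: the
    ratio of each (group, reference) pair at 2-dp half-up rounding, None when
    the reference (or group) prevalence is zero."""
    out: list[float | None] = []
    for pct_group, pct_ref in pairs:
        if pct_group < 0 or pct_ref < 0:
            raise ValueError("percentages must be non-negative")
        if pct_group == 0 or pct_ref == 0:
            out.append(None)
        else:
            out.append(round_half_up(pct_group / pct_ref, 2))
    return out
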
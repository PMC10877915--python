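"""Phase and group comparison battery.

Continuous outcomes (procedure time) are compared by the pooled-variance
two-sample Student t-test; binary outcomes (perforation, piecemeal
resection, detrusor-muscle absence) by the uncorrected Pearson
chi-squared test on a 2×2 table, with Fisher's exact test available as
an alternative. The Yates continuity correction is off by default: the
published p-values this pipeline reproduces (e.g. 0.316 for 16/64 vs
9/52 and 0.269 for 1/56 vs 0/68) match the uncorrected statistic, not
the corrected one. No multiple-testing adjustment is applied; each p is
reported marginally at α = 0.05.

Reports come in two layouts: phase-within-group (initial vs
consolidation, separately per seniority group) and group-within-phase
(junior vs senior, separately per phase), plus overall counts and rates.
Display p-values are formatted to three decimals, with values below
0.0005 rendered "0.000" and binary rows where neither side has any
events rendered "—".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .learning_curve import InflectionResult, segment_phases
from .log_io import ProcedureLog


@dataclass(frozen=True)
class SummaryStat:
    """Mean ± sd summary of a sample of size n (sd with ddof=1)."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "SummaryStat":
        x = np.asarray(values, dtype=float)
        if x.size < 2:
            raise ValueError(f"need at least 2 values, got {x.size}")
        return cls(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=int(x.size))


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Event/non-event counts for two groups: rows (a,b) and (c,d)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise ValueError("each row must have a positive total")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    test_name: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value must lie in [0, 1], got {self.p_value}")


def pooled_t_test(s1: SummaryStat, s2: SummaryStat) -> TestResult:
    """Equal-variance two-sample Student t-test from summary statistics.

    Pooled variance ((n1−1)sd1² + (n2−1)sd2²)/(n1+n2−2); df = n1+n2−2;
    two-sided p. Degenerate zero-variance inputs: equal means → p = 1,
    unequal means → p = 0.
    """
    df = s1.n + s2.n - 2
    if s1.sd == 0.0 and s2.sd == 0.0:
        if s1.mean == s2.mean:
            return TestResult(0.0, df, 1.0, "pooled_t")
        return TestResult(math.inf if s1.mean > s2.mean else -math.inf, df, 0.0, "pooled_t")
    t, p = stats.ttest_ind_from_stats(
        s1.mean, s1.sd, s1.n, s2.mean, s2.sd, s2.n, equal_var=True
    )
    return TestResult(float(t), float(df), float(p), "pooled_t")


def t_test_from_raw(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pooled t-test on raw samples; identical to the summary-stat path."""
    return pooled_t_test(SummaryStat.from_values(x), SummaryStat.from_values(y))


def chi_square_2x2(table: ContingencyTable2x2, correction: bool = False) -> TestResult:
    """Pearson chi-squared test on a 2×2 table, df = 1.

    Uncorrected by default (no Yates continuity correction). A zero
    column marginal (no events at all, or all events) carries no
    information: χ² = 0, p = 1 by convention.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a + c == 0 or b + d == 0:
        return TestResult(0.0, 1.0, 1.0, "chi_square")
    chi2, p, df, _ = stats.chi2_contingency([[a, b], [c, d]], correction=correction)
    return TestResult(float(chi2), float(df), float(p), "chi_square")


def fisher_exact_2x2(table: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher's exact test by hypergeometric enumeration.

    Conditioning on the margins, the count a follows a hypergeometric
    law; the two-sided p sums the probabilities of every table (same
    margins) whose probability does not exceed the observed table's,
    within a relative tolerance of 1e-7. The statistic field carries the
    observed table's hypergeometric probability; df is reported as 0.

    Exact integer arithmetic throughout (the tolerance applies to the
    integer numerators, whose ratios equal the probability ratios).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, c1 = a + b, c + d, a + c
    n = table.n
    lo, hi = max(0, c1 - r2), min(r1, c1)
    numerators = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
    denom = math.comb(n, c1)
    obs = numerators[a - lo]
    cutoff = obs + obs * 1e-7
    p_num = sum(num for num in numerators if num <= cutoff)
    p = min(p_num / denom, 1.0)
    return TestResult(obs / denom, 0.0, p, "fisher_exact")


@dataclass
class OverallSummary:
    """Whole-log counts and rates plus the grand time summary."""

    n: int
    time: SummaryStat
    perforation_count: int
    perforation_pct: float
    piecemeal_count: int
    piecemeal_pct: float
    dm_present_count: int
    dm_present_pct: float
    dm_absent_count: int
    dm_absent_pct: float


def overall_summary(log: ProcedureLog) -> OverallSummary:
    """Aggregate counts and rates over an entire log (rates as percent,
    rounded to two decimals)."""
    if not log.records:
        raise ValueError("cannot summarize an empty log")
    n = len(log.records)
    pct = lambda k: round(100.0 * k / n, 2)
    perf = sum(r.perforation for r in log.records)
    piece = sum(not r.en_bloc for r in log.records)
    dm_pres = sum(r.dm_present for r in log.records)
    times = [r.time_min for r in log.records]
    return OverallSummary(
        n=n,
        time=SummaryStat.from_values(times),
        perforation_count=perf,
        perforation_pct=pct(perf),
        piecemeal_count=piece,
        piecemeal_pct=pct(piece),
        dm_present_count=dm_pres,
        dm_present_pct=pct(dm_pres),
        dm_absent_count=n - dm_pres,
        dm_absent_pct=pct(n - dm_pres),
    )


def format_p(p: Optional[float]) -> str:
    """Three-decimal display; p < 0.0005 renders '0.000'; None renders '—'."""
    if p is None:
        return "—"
    return f"{p:.3f}"


BINARY_VARS = (
    ("perforation", "Perforation", lambda r: r.perforation),
    ("piecemeal", "Piecemeal resection", lambda r: not r.en_bloc),
    ("dm_absent", "DM absent", lambda r: not r.dm_present),
)


@dataclass
class ComparisonReport:
    """Both comparison layouts plus the overall summary.

    ``table`` columns: layout, group_or_phase, variable, cell1, cell2,
    statistic, df, p_raw, p_display. In the phase-within-group layout
    cell1/cell2 are the initial/consolidation cells; in the
    group-within-phase layout they are the junior/senior cells.
    """

    table: pd.DataFrame
    overall: OverallSummary
    inflection_by_group: dict[str, int]
    sample_sizes: dict[str, dict[str, int]]  # group -> phase -> n
    notices: list[str]


def _phase_cells(log: ProcedureLog, group: str, k: int):
    """Split a group's records into phase pools (initial = indices 1..k)."""
    sub = log.select(group)
    by_op: dict[str, list] = {}
    for r in sub.records:
        by_op.setdefault(r.operator_id, []).append(r)
    n_list = {op: max(r.serial_index for r in recs) for op, recs in by_op.items()}
    if len(set(n_list.values())) != 1:
        raise ValueError(f"group {group!r}: operators have unequal series lengths")
    n = next(iter(n_list.values()))
    labels = segment_phases(n, k)
    initial = [r for r in sub.records if labels[r.serial_index - 1] == "initial"]
    consolidation = [r for r in sub.records if labels[r.serial_index - 1] == "consolidation"]
    return initial, consolidation


def _binary_row(recs1, recs2, is_event, binary_test: str):
    a = sum(is_event(r) for r in recs1)
    c = sum(is_event(r) for r in recs2)
    n1, n2 = len(recs1), len(recs2)
    cell1 = f"{100.0 * a / n1:.2f}% ({a}/{n1})"
    cell2 = f"{100.0 * c / n2:.2f}% ({c}/{n2})"
    if a == 0 and c == 0:
        return cell1, cell2, None  # no events on either side: p not defined
    table = ContingencyTable2x2(a, n1 - a, c, n2 - c)
    res = fisher_exact_2x2(table) if binary_test == "fisher" else chi_square_2x2(table)
    return cell1, cell2, res


def _time_row(recs1, recs2):
    cell = lambda recs: f"{np.mean([r.time_min for r in recs]):.2f} ± {np.std([r.time_min for r in recs], ddof=1):.2f}"
    if len(recs1) < 2 or len(recs2) < 2:
        return cell(recs1) if recs1 else "—", cell(recs2) if recs2 else "—", None
    res = t_test_from_raw([r.time_min for r in recs1], [r.time_min for r in recs2])
    return cell(recs1), cell(recs2), res


def compare_phases(
    log: ProcedureLog,
    inflection_by_group: Mapping[str, Union[int, InflectionResult]],
    binary_test: str = "chi_square",
) -> ComparisonReport:
    """Build the full comparison report for a log.

    ``inflection_by_group`` maps each seniority group present in the log
    to its inflection index (or InflectionResult). Procedures are pooled
    across a group's operators into initial/consolidation cells; the
    report contains the phase-within-group layout for every group and,
    when both groups are present, the group-within-phase layout.
    """
    groups = [g for g in ("junior", "senior") if log.select(g).records]
    if not groups:
        raise ValueError("log contains no junior or senior records")
    missing = [g for g in groups if g not in inflection_by_group]
    if missing:
        raise ValueError(f"no inflection provided for group(s) {missing}")

    ks = {
        g: (v.index if isinstance(v := inflection_by_group[g], InflectionResult) else int(v))
        for g in groups
    }
    cells = {g: _phase_cells(log, g, ks[g]) for g in groups}
    sample_sizes = {
        g: {"initial": len(cells[g][0]), "consolidation": len(cells[g][1])} for g in groups
    }

    rows = []

    def add(layout, where, variable, cell1, cell2, res):
        rows.append(
            {
                "layout": layout,
                "group_or_phase": where,
                "variable": variable,
                "cell1": cell1,
                "cell2": cell2,
                "statistic": res.statistic if res else np.nan,
                "df": res.df if res else np.nan,
                "p_raw": res.p_value if res else np.nan,
                "p_display": format_p(res.p_value if res else None),
            }
        )

    # Layout 1: initial vs consolidation, per group
    for g in groups:
        initial, consolidation = cells[g]
        c1, c2, res = _time_row(initial, consolidation)
        add("phase_within_group", g, "Procedure time (min)", c1, c2, res)
        for _, label, is_event in BINARY_VARS:
            c1, c2, res = _binary_row(initial, consolidation, is_event, binary_test)
            add("phase_within_group", g, label, c1, c2, res)

    # Layout 2: junior vs senior, per phase
    notices = []
    if len(groups) == 2:
        for phase, idx in (("initial", 0), ("consolidation", 1)):
            r_j, r_s = cells["junior"][idx], cells["senior"][idx]
            c1, c2, res = _time_row(r_j, r_s)
            add("group_within_phase", phase, "Procedure time (min)", c1, c2, res)
            for _, label, is_event in BINARY_VARS:
                c1, c2, res = _binary_row(r_j, r_s, is_event, binary_test)
                add("group_within_phase", phase, label, c1, c2, res)
    else:
        notices.append(
            f"only one seniority group present ({groups[0]}); group-within-phase layout skipped"
        )

    return ComparisonReport(
        table=pd.DataFrame(rows),
        overall=overall_summary(log),
        inflection_by_group=ks,
        sample_sizes=sample_sizes,
        notices=notices,
    )


def render_text(report: ComparisonReport) -> str:
    """Aligned plain-text rendering of both layouts and the overall rates."""
    lines = []
    ov = report.overall
    lines.append(f"Overall (n = {ov.n})")
    lines.append(f"  Procedure time (min): {ov.time.mean:.2f} ± {ov.time.sd:.2f}")
    lines.append(f"  Perforation: {ov.perforation_count} ({ov.perforation_pct:.2f}%)")
    lines.append(f"  Piecemeal resection: {ov.piecemeal_count} ({ov.piecemeal_pct:.2f}%)")
    lines.append(f"  DM present: {ov.dm_present_count} ({ov.dm_present_pct:.2f}%)")
    lines.append("")

    headers = {
        "phase_within_group": ("Initial phase", "Consolidation phase"),
        "group_within_phase": ("Junior endoscopists", "Senior endoscopists"),
    }
    titles = {
        "phase_within_group": "Procedure parameters for the two learning phases",
        "group_within_phase": "Procedure results for the two groups",
    }
    for layout in ("phase_within_group", "group_within_phase"):
        sub = report.table[report.table["layout"] == layout]
        if sub.empty:
            continue
        lines.append(titles[layout])
        h1, h2 = headers[layout]
        widths = (24, 22, 22, 8)
        for where, block in sub.groupby("group_or_phase", sort=False):
            lines.append(f"  [{where}]")
            lines.append(
                "  "
                + "Variable".ljust(widths[0])
                + h1.ljust(widths[1])
                + h2.ljust(widths[2])
                + "p".ljust(widths[3])
            )
            for _, row in block.iterrows():
                lines.append(
                    "  "
                    + str(row["variable"]).ljust(widths[0])
                    + str(row["cell1"]).ljust(widths[1])
                    + str(row["cell2"]).ljust(widths[2])
                    + str(row["p_display"]).ljust(widths[3])
                )
        lines.append("")
    for notice in report.notices:
        lines.append(f"note: {notice}")
    return "\n".join(lines)
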
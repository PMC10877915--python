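"""Statistical test battery: pooled t, uncorrected chi-squared, Fisher's
exact, overall rates, and the two-layout comparison report."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

from erbt_lc import (
    ContingencyTable2x2,
    ProcedureLog,
    ProcedureRecord,
    SummaryStat,
    chi_square_2x2,
    compare_phases,
    fisher_exact_2x2,
    overall_summary,
    pooled_t_test,
    render_text,
    t_test_from_raw,
)
from erbt_lc.phase_stats import format_p


# ------------------------------------------------------------- t-tests

@pytest.mark.parametrize(
    "s1, s2, p3",
    [
        ((52.61, 10.67, 64), (46.35, 10.17, 52), 0.002),
        ((26.36, 7.39, 56), (23.41, 6.37, 68), 0.019),
    ],
)
def test_pooled_t_published_time_comparisons(s1, s2, p3):
    res = pooled_t_test(SummaryStat(*s1), SummaryStat(*s2))
    assert res.df == s1[2] + s2[2] - 2
    assert round(res.p_value, 3) == p3


def test_pooled_t_identical_summaries():
    s = SummaryStat(10.0, 2.0, 20)
    res = pooled_t_test(s, s)
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_pooled_t_zero_variance_conventions():
    same = pooled_t_test(SummaryStat(5, 0, 4), SummaryStat(5, 0, 4))
    assert same.p_value == 1.0
    diff = t_test_from_raw([0, 0, 0, 0], [1, 1, 1, 1])
    assert diff.p_value == 0.0


def test_t_test_short_sample_rejected():
    with pytest.raises(ValueError):
        t_test_from_raw([1.0], [1.0, 2.0])


@given(
    st.lists(st.floats(-100, 100), min_size=2, max_size=30),
    st.lists(st.floats(-100, 100), min_size=2, max_size=30),
)
def test_raw_and_summary_paths_identical(x, y):
    from_raw = t_test_from_raw(x, y)
    from_summary = pooled_t_test(SummaryStat.from_values(x), SummaryStat.from_values(y))
    assert from_raw == from_summary  # exact, by construction


# --------------------------------------------------------- chi-squared

@pytest.mark.parametrize(
    "table, p3",
    [
        ((16, 48, 9, 43), 0.316),
        ((10, 54, 6, 46), 0.526),
        ((6, 58, 6, 46), 0.704),
        ((1, 55, 0, 68), 0.269),
        ((10, 54, 0, 56), 0.002),
        ((6, 58, 0, 56), 0.019),
        ((6, 46, 0, 68), 0.004),
    ],
)
def test_chi_square_published_cells(table, p3):
    res = chi_square_2x2(ContingencyTable2x2(*table))
    assert res.df == 1
    assert round(res.p_value, 3) == p3


def test_chi_square_closed_form():
    # chi2 = N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))
    a, b, c, d = 16, 48, 9, 43
    n = a + b + c + d
    expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    res = chi_square_2x2(ContingencyTable2x2(a, b, c, d))
    assert res.statistic == pytest.approx(expected)
    assert res.p_value == pytest.approx(sstats.chi2.sf(expected, 1))


def test_chi_square_identical_rows_is_null():
    res = chi_square_2x2(ContingencyTable2x2(5, 5, 5, 5))
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_chi_square_zero_column_marginal_convention():
    res = chi_square_2x2(ContingencyTable2x2(0, 10, 0, 12))
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_chi_square_yates_flag():
    uncorrected = chi_square_2x2(ContingencyTable2x2(16, 48, 9, 43))
    corrected = chi_square_2x2(ContingencyTable2x2(16, 48, 9, 43), correction=True)
    assert corrected.p_value > uncorrected.p_value


small_count = st.integers(0, 30)


@given(small_count, small_count, small_count, small_count)
def test_chi_square_row_and_column_swap_invariance(a, b, c, d):
    if a + b == 0 or c + d == 0:
        return
    base = chi_square_2x2(ContingencyTable2x2(a, b, c, d))
    rows = chi_square_2x2(ContingencyTable2x2(c, d, a, b))
    cols = chi_square_2x2(ContingencyTable2x2(b, a, d, c))
    assert base.p_value == pytest.approx(rows.p_value)
    assert base.statistic == pytest.approx(cols.statistic)


def test_chi_square_monotone_in_association_at_fixed_margins():
    # margins (20, 20 | 20, 20); shift mass along the diagonal
    stats_path = [
        chi_square_2x2(ContingencyTable2x2(10 + s, 10 - s, 10 - s, 10 + s)).statistic
        for s in range(0, 11)
    ]
    assert all(x <= y + 1e-12 for x, y in zip(stats_path, stats_path[1:]))


def test_invalid_table_rejected():
    with pytest.raises(ValueError):
        ContingencyTable2x2(-1, 2, 3, 4)
    with pytest.raises(ValueError):
        ContingencyTable2x2(0, 0, 3, 4)


# ------------------------------------------------------- Fisher's exact

@pytest.mark.parametrize(
    "table, expected_p",
    [
        ((0, 10, 0, 10), 1.0),  # margins admit a single column split only
        ((1, 55, 0, 68), 0.45161290322580644),  # two-table enumeration
        ((5, 0, 0, 5), 1 / 126),  # 2 / C(10,5)
    ],
)
def test_fisher_exact_known_values(table, expected_p):
    res = fisher_exact_2x2(ContingencyTable2x2(*table))
    assert res.p_value == pytest.approx(expected_p, rel=1e-12)
    assert res.df == 0


def test_fisher_statistic_is_observed_table_probability():
    res = fisher_exact_2x2(ContingencyTable2x2(5, 0, 0, 5))
    from math import comb

    assert res.statistic == pytest.approx(comb(5, 5) * comb(5, 0) / comb(10, 5))


@given(small_count, small_count, small_count, small_count)
@settings(max_examples=300)
def test_fisher_matches_scipy_oracle(a, b, c, d):
    if a + b == 0 or c + d == 0 or a + b + c + d > 60:
        return
    res = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
    _, p_scipy = sstats.fisher_exact([[a, b], [c, d]])
    assert res.p_value == pytest.approx(p_scipy, rel=1e-7, abs=1e-12)


# -------------------------------------------------- overall / reports

def _log_with_counts(n=240, perforations=26, piecemeal=16, dm_absent=12):
    """Log of n single-operator-per-group records carrying exact totals."""
    recs = []
    half = n // 2
    for i in range(n):
        op, sen = ("J1", "junior") if i < half else ("S1", "senior")
        recs.append(
            ProcedureRecord(
                op, sen, (i % half) + 1, 30.0 + (i % 7),
                perforation=i < perforations,
                en_bloc=not (i < piecemeal),
                dm_present=not (i < dm_absent),
            )
        )
    return ProcedureLog(recs)


def test_overall_summary_counts_and_rates():
    ov = overall_summary(_log_with_counts())
    assert (ov.perforation_count, ov.perforation_pct) == (26, 10.83)
    assert (ov.piecemeal_count, ov.piecemeal_pct) == (16, 6.67)
    assert (ov.dm_present_count, ov.dm_present_pct) == (228, 95.00)
    assert ov.n == 240


def test_overall_summary_empty_log_rejected():
    with pytest.raises(ValueError):
        overall_summary(ProcedureLog([]))


def test_compare_phases_sample_sizes(step_cohort):
    report = compare_phases(step_cohort, {"junior": 16, "senior": 13})
    assert report.sample_sizes == {
        "junior": {"initial": 64, "consolidation": 56},
        "senior": {"initial": 52, "consolidation": 68},
    }
    # every binary row's cells sum to the phase/group sizes
    sub = report.table[report.table["layout"] == "phase_within_group"]
    for _, row in sub.iterrows():
        if row["variable"] == "Procedure time (min)":
            continue
        n1 = int(row["cell1"].split("/")[1].rstrip(")"))
        n2 = int(row["cell2"].split("/")[1].rstrip(")"))
        sizes = report.sample_sizes[row["group_or_phase"]]
        assert (n1, n2) == (sizes["initial"], sizes["consolidation"])


def test_compare_phases_zero_event_rows_render_dash():
    profiles_events_never = dict(
        p_perforation=(0.0, 0.0), p_piecemeal=(0.0, 0.0), p_dm_absent=(0.0, 0.0)
    )
    from erbt_lc import default_cohort, simulate_cohort

    log = simulate_cohort(default_cohort(shape="step", **profiles_events_never), 1)
    report = compare_phases(log, {"junior": 16, "senior": 13})
    binary = report.table[report.table["variable"] != "Procedure time (min)"]
    assert (binary["p_display"] == "—").all()
    assert binary["p_raw"].isna().all()


def test_compare_phases_single_group_skips_group_layout():
    from erbt_lc import junior_profile, simulate_cohort

    log = simulate_cohort([junior_profile(f"J{i}", shape="step") for i in range(4)], 3)
    report = compare_phases(log, {"junior": 16})
    assert (report.table["layout"] == "phase_within_group").all()
    assert report.notices and "skipped" in report.notices[0]


def test_compare_phases_missing_inflection_rejected(step_cohort):
    with pytest.raises(ValueError, match="senior"):
        compare_phases(step_cohort, {"junior": 16})


def test_render_text_mirrors_table_layouts(step_cohort):
    report = compare_phases(step_cohort, {"junior": 16, "senior": 13})
    text = render_text(report)
    assert "Initial phase" in text and "Consolidation phase" in text
    assert "Junior endoscopists" in text and "Senior endoscopists" in text
    assert "Overall (n = 240)" in text


def test_p_value_display_convention():
    assert format_p(0.0004) == "0.000"  # below 0.0005 renders 0.000
    assert format_p(0.0186) == "0.019"
    assert format_p(None) == "—"
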
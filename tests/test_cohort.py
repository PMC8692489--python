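import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from langtraj.cohort import (
    PclSeries,
    baseline_pcl,
    baseline_values,
    build_series,
    eligibility_report,
    estimate_trajectories,
    fit_trajectory,
    select_cross_sectional,
    select_longitudinal,
)
from langtraj.io import validate_cohort

from conftest import (
    TOY_BASELINES,
    TOY_CROSS_SECTIONAL,
    TOY_EXCLUSIONS_LONGITUDINAL,
    TOY_LONGITUDINAL,
)


# ------------------------------------------------------------------ selection

def test_cross_sectional_selection_matches_hand_derivation(toy_cohort):
    report = select_cross_sectional(toy_cohort)
    assert report.included == TOY_CROSS_SECTIONAL
    assert report.excluded == {
        "B": "no_pre_interview_pcl",
        "C": "no_pcl_within_2_years_of_interview",
    }


def test_longitudinal_selection_matches_hand_derivation(toy_cohort):
    report = select_longitudinal(toy_cohort)
    assert report.included == TOY_LONGITUDINAL
    assert report.excluded == TOY_EXCLUSIONS_LONGITUDINAL


def test_selection_is_idempotent_and_reasons_partition(toy_cohort):
    r1 = select_longitudinal(toy_cohort)
    r2 = select_longitudinal(toy_cohort)
    assert r1.included == r2.included and r1.excluded == r2.excluded
    assert set(r1.included).isdisjoint(r1.excluded)
    assert len(r1.included) + len(r1.excluded) == len(toy_cohort.subjects())


def test_eligibility_report_shows_both_sample_definitions(toy_cohort):
    rep = eligibility_report(toy_cohort)
    assert rep["included_cross_sectional"].sum() == len(TOY_CROSS_SECTIONAL)
    assert rep["included_longitudinal"].sum() == len(TOY_LONGITUDINAL)
    # longitudinal sample is nested within the cross-sectional sample
    assert (rep["included_longitudinal"] <= rep["included_cross_sectional"]).all()


# ------------------------------------------------------------------- baseline

def test_baseline_values_match_hand_derivation(toy_cohort):
    got = baseline_values(toy_cohort, TOY_CROSS_SECTIONAL)
    assert got.to_dict() == TOY_BASELINES


def test_baseline_picks_minimum_absolute_offset():
    s = PclSeries("x", [-0.3, 1.0], [40, 30])
    assert baseline_pcl(s) == (40.0, -0.3)


def test_baseline_tie_prefers_pre_interview():
    s = PclSeries("x", [-0.5, 0.5], [44, 46])
    assert baseline_pcl(s) == (44.0, -0.5)


def test_baseline_outside_window_errors():
    with pytest.raises(ValueError, match="within"):
        baseline_pcl(PclSeries("x", [-3.0, 2.5], [30, 40]))


def test_baseline_equals_exhaustive_scan_on_random_series():
    rng = np.random.default_rng(5)
    for _ in range(50):
        t = np.sort(rng.uniform(-2, 2, size=rng.integers(2, 8)))
        t = t[np.abs(t) <= 2]
        if t.size == 0 or np.any(np.diff(t) == 0):
            continue
        y = rng.uniform(17, 85, t.size)
        val, when = baseline_pcl(PclSeries("x", t, y))
        best = min(range(t.size), key=lambda i: (abs(t[i]), t[i]))
        assert (val, when) == (y[best], t[best])


# ----------------------------------------------------------------- trajectory

def test_perfectly_linear_series_is_fit_exactly():
    est = fit_trajectory(PclSeries("x", [1.0, 2.0, 3.0], [32, 34, 36]))
    assert est.slope == pytest.approx(2.0, abs=1e-12)
    assert est.intercept == pytest.approx(30.0, abs=1e-12)
    assert est.n_points == 3 and est.span == pytest.approx(2.0)


def test_constant_series_has_zero_slope():
    est = fit_trajectory(PclSeries("x", [0.5, 1.0, 5.0], [30, 30, 30]))
    assert est.slope == pytest.approx(0.0, abs=1e-12)


def test_only_post_interview_points_enter_the_fit():
    # the pre-interview observation (t=-1, 80) must not influence the line
    est = fit_trajectory(PclSeries("x", [-1.0, 1.0, 2.0, 3.0], [80, 32, 34, 36]))
    assert est.slope == pytest.approx(2.0, abs=1e-12)
    assert est.n_points == 3


@given(st.integers(0, 10_000))
def test_slope_matches_closed_form(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 9))
    t = np.sort(rng.uniform(0.1, 7, n))
    if np.any(np.diff(t) <= 0):
        t = np.cumsum(rng.uniform(0.1, 1, n))
    y = rng.uniform(17, 85, n)
    est = fit_trajectory(PclSeries("x", t, y))
    tc, yc = t - t.mean(), y - y.mean()
    assert est.slope == pytest.approx(float(tc @ yc / (tc @ tc)), abs=1e-10)
    assert est.intercept == pytest.approx(float(y.mean() - est.slope * t.mean()), abs=1e-10)


def test_time_shift_changes_intercept_not_slope():
    t = np.array([0.5, 1.5, 3.0, 4.0])
    y = np.array([30.0, 35.0, 33.0, 40.0])
    a = fit_trajectory(PclSeries("x", t, y))
    b = fit_trajectory(PclSeries("x", t + 1.0, y))
    assert b.slope == pytest.approx(a.slope, abs=1e-10)
    assert b.intercept == pytest.approx(a.intercept - a.slope, abs=1e-9)


def test_degenerate_series_error():
    with pytest.raises(ValueError, match="post-interview"):
        fit_trajectory(PclSeries("x", [-1.0, 0.5], [30, 40]))


def test_exclude_baseline_from_slope_flag():
    # baseline at +0.5 y; with the flag it leaves the fit
    s = PclSeries("x", [0.5, 1.0, 2.0, 3.0], [60, 32, 34, 36])
    with_base = fit_trajectory(s)
    without = fit_trajectory(s, exclude_baseline_from_slope=True)
    assert with_base.n_points == 4 and without.n_points == 3
    assert without.slope == pytest.approx(2.0, abs=1e-12)


def test_trajectories_invariant_to_row_order(toy_cohort):
    shuffled = validate_cohort(
        toy_cohort.df.sample(frac=1, random_state=1).reset_index(drop=True))
    a = estimate_trajectories(toy_cohort, TOY_LONGITUDINAL)
    b = estimate_trajectories(shuffled, TOY_LONGITUDINAL)
    pd.testing.assert_frame_equal(a, b)


def test_build_series_uses_day_over_year_convention(toy_cohort):
    series = build_series(toy_cohort)["A"]
    assert series.times[0] == pytest.approx(-365 / 365.25)
    assert series.times[-1] == pytest.approx(1278 / 365.25)
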
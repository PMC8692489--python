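"""Sample selection, baseline PCL choice and per-subject trajectory slopes.

Eligibility rules:

* cross-sectional — at least one PCL within ±2 years of the interview and at
  least one strictly pre-interview PCL;
* longitudinal — cross-sectionally eligible, with ≥3 post-interview PCLs and
  the last of them ≥2 years after the interview.

The baseline is the PCL closest in time to the interview (within ±2 years);
an exact pre/post tie prefers the pre-interview value, which cannot be
contaminated by post-interview events.  The trajectory is the per-subject
ordinary-least-squares slope of post-interview PCL on years since interview:
positive slopes mean worsening symptoms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DAYS_PER_YEAR, CohortTable

#: "Within 2 years" is closed on both sides: |Δt| ≤ 2.0 years.
BASELINE_WINDOW_YEARS = 2.0
#: Longitudinal rule: last post-interview PCL at ≥ 2.0 years (inclusive).
MIN_FOLLOWUP_YEARS = 2.0
MIN_POST_INTERVIEW_POINTS = 3


@dataclass
class PclSeries:
    """One subject's PCL observations, times in signed years since interview."""

    subject_id: str
    times: np.ndarray   # strictly increasing
    pcl: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.pcl = np.asarray(self.pcl, dtype=float)
        if self.times.size == 0:
            raise ValueError(f"subject {self.subject_id}: empty PCL series")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError(f"subject {self.subject_id}: times not strictly increasing")

    def post_interview(self) -> tuple[np.ndarray, np.ndarray]:
        mask = self.times > 0
        return self.times[mask], self.pcl[mask]


@dataclass(frozen=True)
class TrajectoryEstimate:
    subject_id: str
    slope: float       # PCL units per year
    intercept: float   # PCL units at the interview date
    n_points: int
    span: float        # years between first and last fitted point


@dataclass
class SelectionReport:
    """Included subject ids plus one primary exclusion reason per dropped subject."""

    included: list[str]
    excluded: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"subject_id": s, "included": True, "exclusion_reason": ""} for s in self.included]
        rows += [{"subject_id": s, "included": False, "exclusion_reason": r}
                 for s, r in sorted(self.excluded.items())]
        return pd.DataFrame(rows).sort_values("subject_id").reset_index(drop=True)


def build_series(cohort: CohortTable) -> dict[str, PclSeries]:
    """Per-subject PCL series; elapsed time is (assessment − interview) days / 365.25."""
    out = {}
    for sid, rows in cohort.df.groupby("subject_id"):
        t = np.array([
            (a - i).days / DAYS_PER_YEAR
            for a, i in zip(rows["assessment_date"], rows["interview_date"])
        ])
        order = np.argsort(t)
        out[str(sid)] = PclSeries(str(sid), t[order], rows["pcl"].to_numpy(dtype=float)[order])
    return out


def _cross_sectional_reason(series: PclSeries) -> str | None:
    if not np.any(np.abs(series.times) <= BASELINE_WINDOW_YEARS):
        return "no_pcl_within_2_years_of_interview"
    if not np.any(series.times < 0):
        return "no_pre_interview_pcl"
    return None


def select_cross_sectional(cohort: CohortTable) -> SelectionReport:
    series_map = build_series(cohort)
    included, excluded = [], {}
    for sid in sorted(series_map):
        reason = _cross_sectional_reason(series_map[sid])
        if reason is None:
            included.append(sid)
        else:
            excluded[sid] = reason
    return SelectionReport(included, excluded)


def select_longitudinal(cohort: CohortTable) -> SelectionReport:
    """Cross-sectional rules plus the follow-up requirements.

    With the interview-proximal baseline this guarantees each retained
    subject contributes at least four data points overall.
    """
    series_map = build_series(cohort)
    included, excluded = [], {}
    for sid in sorted(series_map):
        s = series_map[sid]
        reason = _cross_sectional_reason(s)
        if reason is None:
            post_t, _ = s.post_interview()
            if post_t.size < MIN_POST_INTERVIEW_POINTS:
                reason = "fewer_than_three_post_interview_pcl"
            elif post_t.max() < MIN_FOLLOWUP_YEARS:
                reason = "last_post_interview_pcl_within_2_years"
        if reason is None:
            included.append(sid)
        else:
            excluded[sid] = reason
    return SelectionReport(included, excluded)


def baseline_pcl(series: PclSeries) -> tuple[float, float]:
    """(PCL value, signed time) of the observation closest to the interview.

    Only observations within ±2 years qualify; an exact tie in |time|
    between a pre- and a post-interview observation resolves to the
    pre-interview one.
    """
    mask = np.abs(series.times) <= BASELINE_WINDOW_YEARS
    if not mask.any():
        raise ValueError(
            f"subject {series.subject_id}: no PCL within "
            f"{BASELINE_WINDOW_YEARS} years of the interview"
        )
    t, y = series.times[mask], series.pcl[mask]
    # sort key (|t|, t): for equal |t| the negative (pre-interview) time wins
    best = min(range(t.size), key=lambda i: (abs(t[i]), t[i]))
    return float(y[best]), float(t[best])


def fit_trajectory(series: PclSeries, exclude_baseline_from_slope: bool = False) -> TrajectoryEstimate:
    """OLS line through the post-interview PCL observations.

    ``exclude_baseline_from_slope`` drops the baseline observation from the
    fit when the baseline happens to fall after the interview (a
    pre-interview baseline never enters: only t > 0 points are fitted).
    """
    t, y = series.post_interview()
    if exclude_baseline_from_slope:
        _, t_base = baseline_pcl(series)
        if t_base > 0:
            keep = t != t_base
            t, y = t[keep], y[keep]
    if t.size < 2:
        raise ValueError(
            f"subject {series.subject_id}: {t.size} post-interview point(s); "
            "at least 2 required to fit a line"
        )
    if np.ptp(t) == 0:
        raise ValueError(f"subject {series.subject_id}: all fitted times identical")
    slope, intercept = np.polyfit(t, y, 1)
    return TrajectoryEstimate(series.subject_id, float(slope), float(intercept),
                              int(t.size), float(np.ptp(t)))


def estimate_trajectories(
    cohort: CohortTable,
    subjects: list[str] | None = None,
    exclude_baseline_from_slope: bool = False,
) -> pd.DataFrame:
    """Baseline PCL and Eq.-style trajectory fit for each subject.

    Returns a DataFrame indexed by subject with columns
    ``baseline_pcl, baseline_time, slope, intercept, n_points, span``.
    """
    series_map = build_series(cohort)
    if subjects is None:
        subjects = sorted(series_map)
    rows = []
    for sid in subjects:
        s = series_map[sid]
        b_val, b_t = baseline_pcl(s)
        est = fit_trajectory(s, exclude_baseline_from_slope=exclude_baseline_from_slope)
        rows.append({
            "subject_id": sid, "baseline_pcl": b_val, "baseline_time": b_t,
            "slope": est.slope, "intercept": est.intercept,
            "n_points": est.n_points, "span": est.span,
        })
    return pd.DataFrame(rows).set_index("subject_id")


def baseline_values(cohort: CohortTable, subjects: list[str]) -> pd.Series:
    series_map = build_series(cohort)
    return pd.Series(
        {sid: baseline_pcl(series_map[sid])[0] for sid in subjects}, name="baseline_pcl"
    )


def eligibility_report(cohort: CohortTable) -> pd.DataFrame:
    """Audit TSV body: both sample definitions side by side per subject."""
    cs = select_cross_sectional(cohort)
    lg = select_longitudinal(cohort)
    subjects = cohort.subjects()
    return pd.DataFrame({
        "subject_id": subjects,
        "included_cross_sectional": [s in set(cs.included) for s in subjects],
        "included_longitudinal": [s in set(lg.included) for s in subjects],
        "exclusion_reason": [lg.excluded.get(s, "") for s in subjects],
    })
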
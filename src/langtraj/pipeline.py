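"""End-to-end analysis: profiles + cohort table → result tables.

Covariate codings (gender male = 1, occupation police = 1, marital
married = 1) are arbitrary sign conventions; every covariate is
standardized before model fitting, so only reported metadata — not the
coefficients of the assessments — depends on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import association, cohort as cohort_mod
from .assess import ASSESSMENT_NAMES
from .association import TercileCurves
from .io import CohortTable

CODINGS = {"gender": {"male": 1, "female": 0},
           "occupation": {"police": 1, "non-police": 0},
           "marital_status": {"married": 1, "not married": 0}}

CONTROL_COLUMNS = ["age_at_interview", "gender", "occupation", "years_event_to_interview"]

#: The assessments whose tercile curves are plotted in the trajectory figure.
TERCILE_FEATURES = ("fp_plural", "anxiety", "avg_word_length")


@dataclass
class AnalysisResult:
    cross_sectional: pd.DataFrame
    trajectory: pd.DataFrame
    suppression_cross_sectional: pd.DataFrame
    suppression_trajectory: pd.DataFrame
    terciles: dict[str, TercileCurves]
    mediation_trajectory: pd.DataFrame | None
    eligibility: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def tercile_frame(self) -> pd.DataFrame:
        if not self.terciles:
            return pd.DataFrame(columns=["feature", "group", "time", "mean_residual", "n"])
        return pd.concat([c.to_frame() for c in self.terciles.values()], ignore_index=True)


def control_matrix(cohort: CohortTable, subjects: list[str]) -> pd.DataFrame:
    """Demographic controls, numerically coded, one row per subject."""
    demo = cohort.demographics().loc[subjects]
    ctrl = pd.DataFrame(index=demo.index)
    ctrl["age_at_interview"] = demo["age_at_interview"].astype(float)
    ctrl["gender"] = demo["gender"].map(CODINGS["gender"]).astype(float)
    ctrl["occupation"] = demo["occupation"].map(CODINGS["occupation"]).astype(float)
    ctrl["years_event_to_interview"] = demo["years_event_to_interview"].astype(float)
    return ctrl


def marital_vector(cohort: CohortTable, subjects: list[str]) -> pd.Series | None:
    demo = cohort.demographics()
    if "marital_status" not in demo.columns or demo["marital_status"].isna().any():
        return None
    return demo.loc[subjects, "marital_status"].map(CODINGS["marital_status"]).astype(float)


def run_analysis(
    profiles: pd.DataFrame,
    cohort: CohortTable,
    exclude_baseline_from_slope: bool = False,
    tercile_features: tuple[str, ...] = TERCILE_FEATURES,
    features: list[str] | None = None,
) -> AnalysisResult:
    """The full statistical surface on assessed subjects.

    Cross-sectional models run on the ±2-year/pre-interview sample;
    trajectory models on the ≥3-follow-up sample.  Both families are
    BH-adjusted across the nine assessments per model.
    """
    features = list(features or ASSESSMENT_NAMES)
    series_map = cohort_mod.build_series(cohort)

    cs = cohort_mod.select_cross_sectional(cohort)
    cs_subjects = [s for s in cs.included if s in profiles.index]
    baseline = cohort_mod.baseline_values(cohort, cs_subjects)
    cs_controls = control_matrix(cohort, cs_subjects)
    cross_table = association.cross_sectional_analysis(
        profiles.loc[cs_subjects], baseline, cs_controls, features)

    lg = cohort_mod.select_longitudinal(cohort)
    lg_subjects = [s for s in lg.included if s in profiles.index]
    traj = cohort_mod.estimate_trajectories(
        cohort, lg_subjects, exclude_baseline_from_slope=exclude_baseline_from_slope)
    slopes = traj["slope"]
    lg_controls = pd.concat(
        [traj[["baseline_pcl"]], control_matrix(cohort, lg_subjects)], axis=1)
    traj_table = association.trajectory_analysis(
        profiles.loc[lg_subjects], slopes, lg_controls, features)

    cross_a, cross_b = association.split_models(cross_table)
    traj_a, traj_b = association.split_models(traj_table)

    terciles = {}
    for feat in tercile_features:
        if feat in profiles.columns and len(lg_subjects) >= 6:
            terciles[feat] = association.tercile_trajectories(
                feat, profiles.loc[lg_subjects, feat], series_map, traj, lg_controls)

    marital = marital_vector(cohort, lg_subjects)
    mediation = None
    if marital is not None and len(lg_subjects) > 9:
        mediation = association.mediation_check(
            profiles.loc[lg_subjects], slopes, lg_controls, marital,
            controls_table=traj_b, features=features)

    metadata = {
        "codings": CODINGS,
        "time_convention": "elapsed days / 365.25 = years",
        "baseline_window_years": cohort_mod.BASELINE_WINDOW_YEARS,
        "baseline_tie_break": "pre-interview observation wins an exact |t| tie",
        "exclude_baseline_from_slope": exclude_baseline_from_slope,
        "bh_family": "the assessment features, within each model column",
        "n_cross_sectional": len(cs_subjects),
        "n_longitudinal": len(lg_subjects),
    }
    return AnalysisResult(
        cross_sectional=cross_table,
        trajectory=traj_table,
        suppression_cross_sectional=association.suppression_report(cross_a, cross_b),
        suppression_trajectory=association.suppression_report(traj_a, traj_b),
        terciles=terciles,
        mediation_trajectory=mediation,
        eligibility=cohort_mod.eligibility_report(cohort),
        metadata=metadata,
    )
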
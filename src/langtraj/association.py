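"""Standardized OLS association models with FDR control.

The statistical surface: for each of the nine language-based assessments a
two-sided OLS fit of a standardized outcome (baseline PCL severity or the
per-subject trajectory slope) on the standardized assessment, without and
with standardized control covariates.  Because every variable is z-scored,
the no-controls coefficient is exactly the Pearson product-moment
correlation.  p values come from two-sided t tests with n − k residual
degrees of freedom; 95% CIs are t-based Wald intervals; multiplicity within
each model family (the nine assessments) is handled by Benjamini–Hochberg
step-up adjustment at FDR 0.05.

A *suppression effect* is flagged when adding controls increases a
coefficient's magnitude without flipping its sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from statsmodels.stats.multitest import multipletests

from .cohort import PclSeries

FDR_ALPHA = 0.05


def standardize(values, name: str | None = None) -> np.ndarray:
    """z-score with the sample (n−1) standard deviation.

    A constant vector cannot be standardized and is a hard error naming the
    variable — silently passing zeros would fabricate a null association.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("standardize expects a 1-d vector")
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError(f"variable {name or '<unnamed>'} is constant; cannot standardize")
    return (x - x.mean()) / x.std(ddof=1)


def _check_full_rank(design: np.ndarray, names: list[str]) -> None:
    _, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    tol = diag.max() * 1e-10
    bad = [names[i] for i in range(len(names)) if diag[i] < tol]
    if bad:
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def ols(y, X: pd.DataFrame) -> pd.DataFrame:
    """Plain OLS with intercept: coefficients, 95% CI and two-sided p values.

    Returns a DataFrame indexed by ``const`` plus the columns of ``X`` with
    columns ``beta, ci_low, ci_high, p``.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if len(y) <= X.shape[1] + 1:
        raise ValueError(f"need n > k: n={len(y)}, k={X.shape[1] + 1} (incl. intercept)")
    design = sm.add_constant(X, has_constant="raise")
    _check_full_rank(design.to_numpy(dtype=float), list(design.columns))
    res = sm.OLS(y, design).fit()
    ci = res.conf_int(alpha=0.05)
    return pd.DataFrame({
        "beta": res.params,
        "ci_low": ci[0] if isinstance(ci, pd.DataFrame) else ci[:, 0],
        "ci_high": ci[1] if isinstance(ci, pd.DataFrame) else ci[:, 1],
        "p": res.pvalues,
    })


class StandardizedOLS(RegressorMixin, BaseEstimator):
    """OLS over z-scored variables, as an sklearn estimator.

    Fitted attributes
    -----------------
    coef_ : pd.Series — standardized coefficients (no intercept entry)
    intercept_ : float — intercept on the standardized scale (≈0)
    pvalues_ : pd.Series — two-sided t-test p values per coefficient
    conf_int_ : pd.DataFrame — 95% t-based Wald intervals (ci_low, ci_high)
    bse_ : pd.Series — coefficient standard errors
    n_ : int — observations used
    """

    def __init__(self, standardize_x: bool = True, standardize_y: bool = True):
        self.standardize_x = standardize_x
        self.standardize_y = standardize_y

    def fit(self, X, y):
        X = pd.DataFrame(X).astype(float)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        y = np.asarray(y, dtype=float)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have different lengths")
        if X.shape[0] <= X.shape[1] + 1:
            raise ValueError(
                f"need n > number of parameters: n={X.shape[0]}, k={X.shape[1] + 1}"
            )
        self.x_mean_ = X.mean(axis=0)
        self.x_scale_ = X.std(axis=0, ddof=1)
        self.y_mean_ = float(y.mean())
        self.y_scale_ = float(y.std(ddof=1))
        Z = X.copy()
        if self.standardize_x:
            for col in X.columns:
                Z[col] = standardize(X[col].to_numpy(), name=str(col))
        yz = standardize(y, name="outcome") if self.standardize_y else y
        design = sm.add_constant(Z, has_constant="raise")
        _check_full_rank(design.to_numpy(dtype=float), list(design.columns))
        res = sm.OLS(yz, design).fit()
        ci = res.conf_int(alpha=0.05)
        self.results_ = res
        self.intercept_ = float(res.params["const"])
        self.coef_ = res.params.drop("const")
        self.pvalues_ = res.pvalues.drop("const")
        self.bse_ = res.bse.drop("const")
        self.conf_int_ = pd.DataFrame(
            {"ci_low": ci[0], "ci_high": ci[1]}).drop(index="const")
        self.n_ = int(res.nobs)
        self.df_resid_ = int(res.df_resid)
        return self

    def predict(self, X):
        X = pd.DataFrame(X).astype(float)
        Z = X.copy()
        if self.standardize_x:
            for col in X.columns:
                Z[col] = (X[col] - self.x_mean_[col]) / self.x_scale_[col]
        zhat = self.intercept_ + Z.to_numpy(dtype=float) @ self.coef_.to_numpy()
        if self.standardize_y:
            return self.y_mean_ + self.y_scale_ * zhat
        return zhat


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, alpha=FDR_ALPHA, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Association tables
# ---------------------------------------------------------------------------

def association_table(
    outcome: pd.Series,
    profiles: pd.DataFrame,
    controls: pd.DataFrame | None,
    model_tag: str,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """One row per assessment: standardized coefficient of the assessment in
    ``outcome ~ assessment [+ controls]``, BH-adjusted across the family.
    """
    features = list(features or profiles.columns)
    subjects = profiles.index.intersection(outcome.index)
    if controls is not None:
        subjects = subjects.intersection(controls.index)
    y = outcome.loc[subjects]
    rows = []
    for feat in features:
        X = profiles.loc[subjects, [feat]]
        if controls is not None:
            X = pd.concat([X, controls.loc[subjects]], axis=1)
        est = StandardizedOLS().fit(X, y)
        rows.append({
            "feature": feat,
            "beta": float(est.coef_[feat]),
            "ci_low": float(est.conf_int_.loc[feat, "ci_low"]),
            "ci_high": float(est.conf_int_.loc[feat, "ci_high"]),
            "p": float(est.pvalues_[feat]),
            "model": model_tag,
            "n": est.n_,
        })
    table = pd.DataFrame(rows)
    table["p_bh"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["p_bh"] < FDR_ALPHA
    return table[["feature", "beta", "ci_low", "ci_high", "p", "p_bh",
                  "significant", "model", "n"]]


def cross_sectional_analysis(
    profiles: pd.DataFrame,
    baseline: pd.Series,
    controls: pd.DataFrame,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Concurrent severity: baseline PCL on each assessment, without and
    with controls (age, gender, occupation, years since the event)."""
    a = association_table(baseline, profiles, None, "no_controls", features)
    b = association_table(baseline, profiles, controls, "controls", features)
    return pd.concat([a, b], ignore_index=True)


def trajectory_analysis(
    profiles: pd.DataFrame,
    slopes: pd.Series,
    controls: pd.DataFrame,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Prospective change: trajectory slope on each assessment; the adjusted
    model additionally controls baseline PCL (passed inside ``controls``)."""
    a = association_table(slopes, profiles, None, "no_controls", features)
    b = association_table(slopes, profiles, controls, "controls", features)
    return pd.concat([a, b], ignore_index=True)


def mediation_check(
    profiles: pd.DataFrame,
    outcome: pd.Series,
    controls: pd.DataFrame,
    marital: pd.Series | None,
    controls_table: pd.DataFrame | None = None,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Re-fit the adjusted model with marital status as an extra covariate.

    Answers whether pronoun-style effects merely proxy marital status: a
    feature genuinely predictive beyond marital status stays significant.
    """
    if marital is None:
        raise ValueError("marital status column is required for the mediation check")
    controls_m = pd.concat([controls, marital.rename("marital_status")], axis=1)
    table = association_table(outcome, profiles, controls_m, "controls+marital", features)
    if controls_table is not None:
        prev = controls_table.set_index("feature")["significant"]
        table["was_significant_with_controls"] = table["feature"].map(prev).astype(bool)
        table["stays_significant"] = table["significant"] & table["was_significant_with_controls"]
    return table


def suppression_report(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    """Flag features whose coefficient grows in magnitude, same sign, once
    controls enter the model (classical suppression)."""
    a = table_a.set_index("feature")["beta"]
    b = table_b.set_index("feature")["beta"]
    feats = [f for f in a.index if f in b.index]
    rows = []
    for f in feats:
        same_sign = np.sign(a[f]) == np.sign(b[f])
        rows.append({
            "feature": f,
            "beta_no_controls": float(a[f]),
            "beta_controls": float(b[f]),
            "delta_abs": float(abs(b[f]) - abs(a[f])),
            "suppression": bool(same_sign and abs(b[f]) > abs(a[f])),
        })
    return pd.DataFrame(rows)


def split_models(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(no_controls rows, controls rows) of a stacked association table."""
    return (table[table["model"] == "no_controls"].reset_index(drop=True),
            table[table["model"] == "controls"].reset_index(drop=True))


# ---------------------------------------------------------------------------
# Tercile trajectory curves
# ---------------------------------------------------------------------------

@dataclass
class TercileCurves:
    """Mean control-adjusted PCL residual trajectories for the top and
    bottom thirds of subjects ranked by one assessment."""

    feature: str
    grid: np.ndarray
    mean_top: np.ndarray      # NaN where no subject's span covers the grid point
    mean_bottom: np.ndarray
    n_top: int
    n_bottom: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for group, curve, n in (("top", self.mean_top, self.n_top),
                                ("bottom", self.mean_bottom, self.n_bottom)):
            for t, v in zip(self.grid, curve):
                rows.append({"feature": self.feature, "group": group,
                             "time": float(t), "mean_residual": float(v), "n": n})
        return pd.DataFrame(rows)


def _group_mean_curve(
    subjects: list[str],
    series_map: dict[str, PclSeries],
    pred_intercept: pd.Series,
    pred_slope: pd.Series,
    grid: np.ndarray,
) -> np.ndarray:
    total = np.zeros_like(grid)
    count = np.zeros_like(grid)
    for sid in subjects:
        t, y = series_map[sid].post_interview()
        if t.size < 2:
            continue
        inside = (grid >= t.min()) & (grid <= t.max())  # interpolate within span only
        obs = np.interp(grid[inside], t, y)
        expected = pred_intercept[sid] + pred_slope[sid] * grid[inside]
        total[inside] += obs - expected
        count[inside] += 1
    with np.errstate(invalid="ignore"):
        return np.where(count > 0, total / np.maximum(count, 1), np.nan)


def tercile_trajectories(
    feature: str,
    feature_values: pd.Series,
    series_map: dict[str, PclSeries],
    trajectories: pd.DataFrame,
    controls: pd.DataFrame,
    n_grid: int = 25,
) -> TercileCurves:
    """Fig.-style curves: rank subjects by an assessment, take top and bottom
    terciles, and average their control-adjusted trajectory residuals.

    The expected trajectory of each subject is predicted from controls-only
    models of the per-subject intercepts and slopes; the residual at time t
    is the (linearly interpolated) observed PCL minus that prediction.
    """
    subjects = [s for s in feature_values.index
                if s in series_map and s in trajectories.index and s in controls.index]
    if len(subjects) < 6:
        raise ValueError(f"need at least 6 subjects for terciles, got {len(subjects)}")
    values = feature_values.loc[subjects]
    order = values.to_numpy().argsort(kind="stable")  # stable: ties keep subject order
    k = len(subjects) // 3
    bottom = [subjects[i] for i in order[:k]]
    top = [subjects[i] for i in order[-k:]]

    ctrl = controls.loc[subjects]
    pred_int = pd.Series(
        StandardizedOLS(standardize_y=False).fit(ctrl, trajectories.loc[subjects, "intercept"]).predict(ctrl),
        index=subjects)
    pred_slope = pd.Series(
        StandardizedOLS(standardize_y=False).fit(ctrl, trajectories.loc[subjects, "slope"]).predict(ctrl),
        index=subjects)

    t_max = max(series_map[s].post_interview()[0].max() for s in subjects)
    grid = np.linspace(0.0, float(t_max), n_grid)
    return TercileCurves(
        feature=feature,
        grid=grid,
        mean_top=_group_mean_curve(top, series_map, pred_int, pred_slope, grid),
        mean_bottom=_group_mean_curve(bottom, series_map, pred_int, pred_slope, grid),
        n_top=len(top),
        n_bottom=len(bottom),
    )
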
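import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from sklearn.base import clone

from langtraj.association import (
    StandardizedOLS,
    association_table,
    bh_adjust,
    cross_sectional_analysis,
    mediation_check,
    ols,
    split_models,
    standardize,
    suppression_report,
    tercile_trajectories,
)
from langtraj.cohort import PclSeries, build_series, estimate_trajectories
from langtraj.pipeline import run_analysis
from langtraj.synthetic import GeneratorConfig, simulate_assessments


def brute_force_bh(p):
    """Step-up definition: adj_(i) = min_{j>=i} min(1, p_(j) * m / j)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    for rank_i in range(m):
        adj_sorted[rank_i] = min(
            min(1.0, p[order[j]] * m / (j + 1)) for j in range(rank_i, m)
        )
    out = np.empty(m)
    out[order] = adj_sorted
    return out


# -------------------------------------------------------------- standardize

def test_standardize_example():
    np.testing.assert_allclose(standardize([1, 2, 3]), [-1, 0, 1])


def test_standardize_constant_vector_names_variable():
    with pytest.raises(ValueError, match="pcl"):
        standardize([5, 5, 5], name="pcl")


def test_standardize_identity():
    z = standardize(np.random.default_rng(0).normal(3, 7, 100))
    assert abs(z.mean()) < 1e-12 and abs(z.std(ddof=1) - 1) < 1e-12


# ----------------------------------------------------------------------- OLS

def test_exact_linear_relation_recovered():
    x = np.arange(10.0)
    table = ols(2 * x, pd.DataFrame({"x": x}))
    assert table.loc["x", "beta"] == pytest.approx(2.0, abs=1e-12)
    assert table.loc["x", "p"] < 1e-12


def test_rank_deficiency_names_collinear_column():
    x = np.arange(10.0)
    X = pd.DataFrame({"x": x, "x2": 2 * x})
    with pytest.raises(ValueError, match="x2"):
        ols(np.random.default_rng(0).normal(size=10), X)


def test_standardized_single_predictor_beta_is_pearson_r():
    rng = np.random.default_rng(1)
    x = rng.normal(size=80)
    y = 0.5 * x + rng.normal(size=80)
    est = StandardizedOLS().fit(pd.DataFrame({"x": x}), y)
    assert est.coef_["x"] == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-10)
    assert est.conf_int_.loc["x", "ci_low"] <= est.coef_["x"] <= est.conf_int_.loc["x", "ci_high"]


def test_standardized_ols_is_sklearn_compatible():
    rng = np.random.default_rng(2)
    X = pd.DataFrame({"a": rng.normal(size=60), "b": rng.normal(size=60)})
    y = X["a"].to_numpy() + rng.normal(size=60)
    est = clone(StandardizedOLS()).fit(X, y)
    assert est.n_features_in_ == 2
    assert est.predict(X).shape == (60,)
    # prediction returns to the outcome's original scale
    assert abs(est.predict(X).mean() - y.mean()) < 1e-8


def test_needs_more_observations_than_parameters():
    X = pd.DataFrame(np.random.default_rng(3).normal(size=(4, 3)))
    with pytest.raises(ValueError, match="n"):
        StandardizedOLS().fit(X, np.arange(4.0))


# ------------------------------------------------------------------------ BH

def test_bh_single_p_is_identity():
    np.testing.assert_allclose(bh_adjust([0.05]), [0.05])


def test_bh_hand_example():
    np.testing.assert_allclose(bh_adjust([0.01, 0.5]), [0.02, 0.5])


@given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=9))
def test_bh_matches_brute_force_definition(p):
    np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)


@given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=9))
def test_bh_adjusted_at_least_raw(p):
    assert np.all(bh_adjust(p) >= np.asarray(p) - 1e-15)


# --------------------------------------------------------- association tables

def test_self_regression_beta_is_one():
    rng = np.random.default_rng(4)
    values = pd.Series(rng.normal(size=50), index=[f"s{i}" for i in range(50)])
    profiles = pd.DataFrame({"echo": values})
    table = association_table(values, profiles, None, "no_controls")
    assert table.loc[0, "beta"] == pytest.approx(1.0, abs=1e-10)


def test_two_model_table_has_two_rows_per_feature():
    prof, cohort, _ = simulate_assessments(GeneratorConfig(n_subjects=60, seed=0, words_mean=800))
    res = run_analysis(prof, cohort, tercile_features=())
    assert len(res.cross_sectional) == 18  # 9 features × {no_controls, controls}
    assert set(res.cross_sectional["model"]) == {"no_controls", "controls"}
    sig = res.cross_sectional
    assert ((sig["p_bh"] < 0.05) == sig["significant"]).all()
    assert (sig["p_bh"] >= sig["p"] - 1e-15).all()
    assert ((sig["ci_low"] <= sig["beta"]) & (sig["beta"] <= sig["ci_high"])).all()


# ---------------------------------------------------------------- suppression

def _tables_from(y, x, control, n_label):
    idx = [f"s{i}" for i in range(len(y))]
    outcome = pd.Series(y, index=idx)
    profiles = pd.DataFrame({"feat": x}, index=idx)
    controls = pd.DataFrame({"c": control}, index=idx)
    a = association_table(outcome, profiles, None, "no_controls")
    b = association_table(outcome, profiles, controls, "controls")
    return a, b


def test_classical_suppressor_is_flagged():
    # x = signal + noise; the control measures the noise only: partialling it
    # out purifies x, so |beta| grows with an unchanged sign.
    rng = np.random.default_rng(6)
    signal = rng.normal(size=400)
    noise = rng.normal(size=400)
    x = signal + noise
    a, b = _tables_from(signal, x, noise, 400)
    rep = suppression_report(a, b)
    assert bool(rep.loc[0, "suppression"])
    assert abs(rep.loc[0, "beta_controls"]) > abs(rep.loc[0, "beta_no_controls"]) > 0


def test_shrinking_coefficient_is_not_flagged():
    # classic confounding: control explains both x and y, so beta shrinks
    rng = np.random.default_rng(7)
    confounder = rng.normal(size=400)
    x = confounder + 0.4 * rng.normal(size=400)
    y = confounder + 0.4 * rng.normal(size=400)
    a, b = _tables_from(y, x, confounder, 400)
    rep = suppression_report(a, b)
    assert not bool(rep.loc[0, "suppression"])


# ------------------------------------------------------------------ mediation

def test_independent_marital_status_leaves_significance_unchanged():
    prof, cohort, _ = simulate_assessments(GeneratorConfig(n_subjects=500, seed=1))
    res = run_analysis(prof, cohort, tercile_features=())
    med = res.mediation_trajectory
    assert med is not None
    _, with_controls = split_models(res.trajectory)
    merged = med.merge(with_controls, on="feature", suffixes=("_m", "_c"))
    assert (merged["significant_m"] == merged["significant_c"]).all()


def test_perfect_mediator_collapses_the_coefficient():
    # the feature is a noisy readout of the very trait the mediator measures
    # exactly; once the mediator enters, the feature has nothing left to add
    rng = np.random.default_rng(8)
    m = rng.normal(size=300)
    feat = m + 0.2 * rng.normal(size=300)
    y = m + 0.3 * rng.normal(size=300)
    idx = [f"s{i}" for i in range(300)]
    profiles = pd.DataFrame({"feat": feat}, index=idx)
    outcome = pd.Series(y, index=idx)
    controls = pd.DataFrame({"c": rng.normal(size=300)}, index=idx)
    marital = pd.Series(m, index=idx)
    without = association_table(outcome, profiles, controls, "controls")
    with_m = mediation_check(profiles, outcome, controls, marital)
    assert abs(with_m.loc[0, "beta"]) < 0.1 * abs(without.loc[0, "beta"])


def test_missing_marital_column_is_an_error():
    profiles = pd.DataFrame({"feat": [1.0, 2.0, 3.0]})
    with pytest.raises(ValueError, match="marital"):
        mediation_check(profiles, pd.Series([1.0, 2.0, 3.0]), None, None)


# ------------------------------------------------------------------- terciles

def _tercile_inputs(n, seed, planted=True):
    effects = {"anxiety": (0.0, 0.6)} if planted else {}
    cfg = GeneratorConfig(n_subjects=n, seed=seed, words_mean=2000,
                          planted_effects=effects)
    prof, cohort, _ = simulate_assessments(cfg)
    series_map = build_series(cohort)
    subjects = sorted(series_map)
    traj = estimate_trajectories(cohort, subjects)
    from langtraj.pipeline import control_matrix
    controls = pd.concat([traj[["baseline_pcl"]], control_matrix(cohort, subjects)], axis=1)
    return prof, series_map, traj, controls


def test_terciles_split_nine_subjects_three_ways():
    prof, series_map, traj, controls = _tercile_inputs(9, 0)
    curves = tercile_trajectories("anxiety", prof["anxiety"], series_map, traj, controls)
    assert curves.n_top == curves.n_bottom == 3


def test_planted_worsening_signal_separates_tercile_curves():
    prof, series_map, traj, controls = _tercile_inputs(150, 2)
    curves = tercile_trajectories("anxiety", prof["anxiety"], series_map, traj, controls)
    gap = curves.mean_top - curves.mean_bottom
    finite = np.isfinite(gap)
    # anxious-language top tercile worsens relative to the bottom tercile
    assert gap[finite][-1] > 0
    frame = curves.to_frame()
    assert set(frame["group"]) == {"top", "bottom"}
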
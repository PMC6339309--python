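"""Pseudo-class draws, clustered logistic regression, Rubin pooling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import latclass as lc
from latclass.pooling import SeparationError, _design_matrices


# ---------------------------------------------------------------------------
# pseudo-class draws
# ---------------------------------------------------------------------------

def test_degenerate_posterior_gives_constant_draws():
    tau = np.tile([1.0, 0.0], (7, 1))
    draws = lc.draw_pseudo_classes(tau, n_imputations=5, seed=0)
    assert (draws.draws == 1).all()
    assert (draws.modal == 1).all()


def test_draws_reproduce_posterior_marginally():
    tau = np.array([[0.5, 0.5]])
    draws = lc.draw_pseudo_classes(tau, n_imputations=10_000, seed=1)
    frac1 = (draws.draws == 1).mean()
    assert frac1 == pytest.approx(0.5, abs=0.015)


@settings(deadline=None, derandomize=True, max_examples=20)
@given(st.integers(min_value=0, max_value=10_000))
def test_draw_frequencies_track_tau(seed):
    rng = np.random.default_rng(seed)
    tau = rng.dirichlet(np.ones(3), size=5)
    draws = lc.draw_pseudo_classes(tau, n_imputations=3000, seed=seed)
    freq = np.stack([(draws.draws == k + 1).mean(axis=1) for k in range(3)]).T
    np.testing.assert_allclose(freq, tau, atol=0.05)


def test_draws_deterministic_given_seed():
    tau = np.random.default_rng(4).dirichlet(np.ones(2), size=40)
    a = lc.draw_pseudo_classes(tau, 5, seed=42)
    b = lc.draw_pseudo_classes(tau, 5, seed=42)
    np.testing.assert_array_equal(a.draws, b.draws)


def test_modal_membership_majority_and_ties():
    draws = lc.PseudoClassDraws(np.array([[1, 1, 2, 1, 2],
                                          [2, 2, 2, 2, 2]]))
    assert lc.modal_membership(draws).tolist() == [1, 2]
    assert not draws.tie_flags.any()        # odd M, K=2: no ties possible
    tied = lc.PseudoClassDraws(np.array([[1, 2]]))
    assert tied.modal.tolist() == [1]       # tie -> lower label, flagged
    assert tied.tie_flags.all()


def test_class_by_demographics(study_dataset):
    ds, _ = study_dataset
    labels = np.ones(ds.n, dtype=int)
    table = lc.class_by_demographics(labels, ds)
    filled = table[table["n"] > 0]
    assert (filled["proportion"] == 1.0).all()
    assert (filled["se"] == 0.0).all()
    # binomial SE formula on a mixed stratum
    labels[: ds.n // 2] = 2
    table = lc.class_by_demographics(labels, ds)
    row = table[table["variable"] == "overall"].iloc[0]
    p, n = row["proportion"], row["n"]
    assert row["se"] == pytest.approx(np.sqrt(p * (1 - p) / n))
    assert ((0 <= filled["proportion"]) & (filled["proportion"] <= 1)).all()


# ---------------------------------------------------------------------------
# clustered logistic regression
# ---------------------------------------------------------------------------

def _contingency_dataset():
    # exposed: 30 events / 20 non; unexposed: 10 events / 40 non
    y = np.r_[np.ones(30), np.zeros(20), np.ones(10), np.zeros(40)]
    x = np.r_[np.ones(50), np.zeros(50)]
    return y, pd.DataFrame({"x": x})


def test_logit_coefficient_is_log_odds_ratio():
    y, X = _contingency_dataset()
    fit = lc.fit_cluster_logit(y, X, clusters=np.arange(100))
    expected = np.log((30 * 40) / (20 * 10))
    assert fit.params["x"] == pytest.approx(expected, abs=1e-6)
    assert fit.n_obs == 100 and fit.n_clusters == 100 and fit.n_dropped == 0


def test_singleton_clusters_match_hc_sandwich():
    """One cluster per row degenerates to the heteroskedasticity-robust
    sandwich (times the G/(G-1) factor)."""
    import statsmodels.api as sm
    y, X = _contingency_dataset()
    fit = lc.fit_cluster_logit(y, X, clusters=np.arange(100))
    Xc = sm.add_constant(X)
    hc = sm.Logit(y, Xc).fit(disp=0, cov_type="HC0")
    expected = np.sqrt(np.diag(hc.cov_params()) * 100 / 99)
    np.testing.assert_allclose(fit.bse.to_numpy(), expected, rtol=1e-6)


def test_separation_detected():
    y = np.r_[np.ones(30), np.zeros(30)]
    X = pd.DataFrame({"x": y.copy()})       # perfect separation
    with pytest.raises(SeparationError, match="x"):
        lc.fit_cluster_logit(y, X, clusters=np.arange(60))


def test_single_cluster_rejected():
    y, X = _contingency_dataset()
    with pytest.raises(ValueError, match="clusters"):
        lc.fit_cluster_logit(y, X, clusters=np.zeros(100))


def test_complete_case_rows_counted():
    y, X = _contingency_dataset()
    X.loc[:4, "x"] = np.nan
    fit = lc.fit_cluster_logit(y, X, clusters=np.arange(100))
    assert fit.n_dropped == 5 and fit.n_obs == 95


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------

def _fake_fit(coefs, variances, n_obs=100):
    idx = [f"b{i}" for i in range(len(coefs))]
    return lc.ClusterLogitFit(
        params=pd.Series(coefs, index=idx),
        cov=pd.DataFrame(np.diag(variances), index=idx, columns=idx),
        n_obs=n_obs, n_clusters=50, n_dropped=0)


def test_rubin_closed_form_example():
    fits = [_fake_fit([q], [1.0]) for q in [0, 1, 2, 3, 4]]
    pooled = lc.pool_rubin(fits).table.iloc[0]
    assert pooled["coef"] == pytest.approx(2.0)
    assert pooled["within_var"] == pytest.approx(1.0)
    assert pooled["between_var"] == pytest.approx(2.5)
    assert pooled["total_var"] == pytest.approx(4.0)


def test_rubin_identical_estimates_collapse():
    fits = [_fake_fit([0.7], [0.04]) for _ in range(5)]
    row = lc.pool_rubin(fits).table.iloc[0]
    assert row["between_var"] == 0.0
    assert row["total_var"] == pytest.approx(row["within_var"])
    # with B=0 the CI is the single-fit normal CI
    assert row["or_ci_low"] == pytest.approx(np.exp(0.7 - 1.96 * 0.2), rel=1e-3)


def test_rubin_mismatched_names_error():
    a = _fake_fit([1.0], [1.0])
    b = lc.ClusterLogitFit(params=pd.Series([1.0], index=["other"]),
                           cov=pd.DataFrame([[1.0]], index=["other"],
                                            columns=["other"]),
                           n_obs=100, n_clusters=50, n_dropped=0)
    with pytest.raises(ValueError, match="mismatched"):
        lc.pool_rubin([a, b])


@settings(deadline=None, derandomize=True, max_examples=20)
@given(st.integers(min_value=0, max_value=10_000))
def test_rubin_variance_identities(seed):
    """T >= W, B >= 0, CI contains the pooled OR; T grows with B."""
    rng = np.random.default_rng(seed)
    coefs = rng.normal(0, 1, size=5)
    variances = rng.uniform(0.01, 1.0, size=5)
    fits = [_fake_fit([c], [v]) for c, v in zip(coefs, variances)]
    row = lc.pool_rubin(fits).table.iloc[0]
    assert row["between_var"] >= 0
    assert row["total_var"] >= row["within_var"] - 1e-12
    assert row["or_ci_low"] <= row["or"] <= row["or_ci_high"]


# ---------------------------------------------------------------------------
# structural pipeline
# ---------------------------------------------------------------------------

def test_pipeline_deterministic_posteriors_give_zero_between(study_dataset):
    ds, _ = study_dataset
    rng = np.random.default_rng(8)
    hard = np.zeros((ds.n, 2))
    hard[np.arange(ds.n), rng.integers(0, 2, ds.n)] = 1.0
    res = lc.LCAResults(
        model=None, class_weights=np.array([0.6, 0.4]),
        item_probs=np.full((5, 2, 3), 1 / 3), posteriors=hard, llf=0.0,
        n_params=21, bic=0.0, rel_entropy=1.0, converged=True,
        start_logliks=np.array([0.0]))
    out = lc.run_structural_pipeline(res, ds, n_imputations=5, seed=3,
                                     models=("unadjusted",))
    assert (out["unadjusted"].pooled.table["between_var"] == 0).all()


def test_pipeline_seeded_reproducibility(study_fit, study_dataset):
    ds, _ = study_dataset
    a = lc.run_structural_pipeline(study_fit, ds, seed=9)
    b = lc.run_structural_pipeline(study_fit, ds, seed=9)
    for name in ("unadjusted", "adjusted"):
        pd.testing.assert_frame_equal(a[name].pooled.table,
                                      b[name].pooled.table)


def test_design_matrix_referent_coding(study_dataset):
    ds, _ = study_dataset
    X = _design_matrices(ds, adjusted=True)
    assert list(X.columns) == [
        "basic_sanitation", "edu_primary", "edu_less_than_secondary",
        "edu_secondary", "afro_ecuadorian", "female", "cement_walls",
        "non_asset_deprived"]
    edu = ds.covariates["education"]
    ref_rows = edu == "less_than_primary"
    assert (X.loc[ref_rows.to_numpy(),
                  ["edu_primary", "edu_less_than_secondary",
                   "edu_secondary"]].to_numpy() == 0).all()
    assert X["cement_walls"].isna().sum() == (
        ds.covariates["cement_walls"] == "missing").sum()


def test_pipeline_recovers_exposure_effect():
    """A built-in class-exposure log-odds of log(2) comes back as a pooled
    OR near 2 on average."""
    model = lc.reference_model(exposure_effect=np.log(2.0))
    ors = []
    for rep in range(25):
        ds, _ = lc.generate_survey(model, n_households=150, seed=900 + rep)
        fit = lc.LatentClassModel.from_dataset(ds, 2).fit(
            n_starts=6, seed=rep, se_method=None)
        out = lc.run_structural_pipeline(fit, ds, seed=rep,
                                         models=("unadjusted",))
        ors.append(out["unadjusted"].pooled.table.loc["basic_sanitation",
                                                      "coef"])
    mean_or = np.exp(np.mean(ors))
    se = np.std(ors, ddof=1) / np.sqrt(len(ors))
    assert np.log(2) - 3 * se < np.mean(ors) < np.log(2) + 3 * se, mean_or
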
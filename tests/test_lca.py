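"""Measurement-model estimation: EM, posteriors, fit statistics, SEs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import latclass as lc
from latclass.lca import (
    ConvergenceError,
    _Parameterization,
    compute_bic,
    n_free_parameters,
    relative_entropy,
)
from conftest import make_results


# ---------------------------------------------------------------------------
# EM estimation
# ---------------------------------------------------------------------------

def test_one_class_fit_is_observed_proportions():
    rng = np.random.default_rng(0)
    resp = rng.integers(0, 3, size=(200, 4)).astype(np.int8)
    fit = lc.LatentClassModel(resp, 1, n_categories=3).fit(n_starts=1, seed=0)
    for j in range(4):
        expected = np.bincount(resp[:, j], minlength=3) / 200
        np.testing.assert_allclose(fit.item_probs[j, 0], expected, atol=1e-8)
    np.testing.assert_allclose(fit.posteriors, 1.0)
    # delta-method SEs collapse to the multinomial proportion formula
    se_expected = np.sqrt(fit.item_probs[:, 0, :]
                          * (1 - fit.item_probs[:, 0, :]) / 200)
    np.testing.assert_allclose(fit.se_item_probs[:, 0, :], se_expected,
                               atol=2e-4)


def test_em_loglik_monotone(study_dataset):
    ds, _ = study_dataset
    fit = lc.LatentClassModel.from_dataset(ds, 2).fit(
        n_starts=3, seed=2, se_method=None)
    diffs = np.diff(fit.em_history)
    assert (diffs >= -1e-9).all()


def test_label_order_and_stability(ref_model):
    """Swapping the generating class labels leaves the fit unchanged."""
    swapped = lc.GenerativeModel(
        pi=ref_model.pi[::-1].copy(), rho=ref_model.rho[:, ::-1, :].copy(),
        indicator_ids=ref_model.indicator_ids)
    a, _ = lc.sample_indicators(ref_model, 2000, seed=5)
    b, _ = lc.sample_indicators(swapped, 2000, seed=5)
    fa = lc.LatentClassModel.from_dataset(a, 2).fit(n_starts=10, seed=1,
                                                    se_method=None)
    fb = lc.LatentClassModel.from_dataset(b, 2).fit(n_starts=10, seed=1,
                                                    se_method=None)
    # regardless of the generating label order, the returned classes are
    # sorted by prevalence and match the sorted truth up to sampling error
    for f in (fa, fb):
        assert f.class_weights[0] >= f.class_weights[1]
        np.testing.assert_allclose(f.class_weights, ref_model.pi, atol=0.05)
        np.testing.assert_allclose(f.item_probs, ref_model.rho, atol=0.09)


def test_parameter_recovery_rmse(ref_model):
    """RMSE of (pi, rho) over repeated N=5000 draws stays below 0.02."""
    errs = []
    for rep in range(20):
        ds, _ = lc.sample_indicators(ref_model, 5000, seed=100 + rep)
        fit = lc.LatentClassModel.from_dataset(ds, 2).fit(
            n_starts=8, seed=rep, se_method=None)
        errs.append(np.concatenate([
            fit.class_weights - ref_model.pi,
            (fit.item_probs - ref_model.rho).ravel()]))
    rmse = np.sqrt(np.mean(np.concatenate(errs) ** 2))
    assert rmse < 0.02


def test_fiml_uses_partial_responses(ref_model):
    """Item nonresponse shrinks but does not break estimation."""
    ds, _ = lc.sample_indicators(ref_model, 4000, seed=3)
    ds.responses[np.random.default_rng(0).random(ds.responses.shape) < 0.15] = -1
    fit = lc.LatentClassModel.from_dataset(ds, 2).fit(
        n_starts=8, seed=4, se_method=None)
    assert abs(fit.class_weights[0] - ref_model.pi[0]) < 0.05


def test_no_convergence_raises(study_dataset):
    ds, _ = study_dataset
    model = lc.LatentClassModel.from_dataset(ds, 2)
    with pytest.raises(ConvergenceError) as err:
        model.fit(n_starts=2, max_iter=2, tol=1e-16, seed=0, se_method=None)
    assert len(err.value.start_logliks) == 2


def test_identifiability_guard():
    resp = np.tile([[0, 1], [1, 0]], (5, 1)).astype(np.int8)  # 2 patterns
    model = lc.LatentClassModel(resp, 3, n_categories=2)
    with pytest.warns(UserWarning, match="identifiable"):
        model.fit(n_starts=2, seed=0, se_method=None)


# ---------------------------------------------------------------------------
# posteriors
# ---------------------------------------------------------------------------

def test_posterior_all_missing_returns_prior():
    res = make_results([0.7, 0.3], np.full((3, 2, 3), 1 / 3))
    tau = res.predict_posterior([-1, -1, -1])
    np.testing.assert_allclose(tau, [0.7, 0.3], atol=1e-9)


def test_posterior_deterministic_pattern():
    rho = np.zeros((2, 2, 3))
    rho[:, 0, 0] = 1.0          # class 1 always agrees
    rho[:, 1, 1] = 1.0          # class 2 always disagrees
    res = make_results([0.5, 0.5], rho)
    tau = res.predict_posterior([0, 0])
    np.testing.assert_allclose(tau, [1.0, 0.0], atol=1e-6)


def test_posterior_matches_hand_bayes():
    # two items, K=2: tau_1 = pi1*r1a*r1b / (pi1*r1a*r1b + pi2*r2a*r2b)
    rho = np.array([[[0.8, 0.15, 0.05], [0.3, 0.5, 0.2]],
                    [[0.6, 0.3, 0.1], [0.2, 0.7, 0.1]]])
    res = make_results([0.6, 0.4], rho)
    tau = res.predict_posterior([0, 1])
    num1 = 0.6 * 0.8 * 0.3
    num2 = 0.4 * 0.3 * 0.7
    np.testing.assert_allclose(tau, [num1 / (num1 + num2),
                                     num2 / (num1 + num2)], atol=1e-9)


def test_posterior_rejects_bad_code():
    res = make_results([1.0], np.full((2, 1, 3), 1 / 3))
    with pytest.raises(ValueError, match="codebook"):
        res.predict_posterior([0, 7])


# ---------------------------------------------------------------------------
# fit statistics
# ---------------------------------------------------------------------------

def test_bic_values():
    assert compute_bic(0.0, 0, 10) == 0.0
    assert compute_bic(-100.0, 5, 100) == pytest.approx(223.03, abs=0.005)
    assert n_free_parameters(2, [3] * 5) == 21


@pytest.mark.parametrize("tau,expected", [
    (np.array([[1.0, 0.0]] * 8), 1.0),
    (np.array([[0.5, 0.5]] * 8), 0.0),
])
def test_relative_entropy_extremes(tau, expected):
    assert relative_entropy(tau) == pytest.approx(expected, abs=1e-12)


def test_relative_entropy_validates_rows():
    with pytest.raises(ValueError):
        relative_entropy(np.array([[0.5, 0.4]]))


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(min_value=0, max_value=10_000))
def test_relative_entropy_invariances(seed):
    """E is unchanged by row permutation and class relabeling, and in [0,1]."""
    rng = np.random.default_rng(seed)
    tau = rng.dirichlet(np.ones(3), size=20)
    e = relative_entropy(tau)
    assert 0.0 <= e <= 1.0
    assert relative_entropy(tau[rng.permutation(20)]) == pytest.approx(e)
    assert relative_entropy(tau[:, rng.permutation(3)]) == pytest.approx(e)


# ---------------------------------------------------------------------------
# standard errors
# ---------------------------------------------------------------------------

def test_boundary_rho_has_zero_se(study_fit):
    rho = study_fit.item_probs
    b = study_fit.boundary
    at_bound = (rho <= 1e-6) | (rho >= 1 - 1e-6)
    np.testing.assert_array_equal(b, at_bound)
    assert (study_fit.se_item_probs[b] == 0).all()
    assert b.any()      # the rainy-season boundary indicator shows up


def test_sandwich_singleton_clusters_equals_hc(study_dataset):
    """With every individual its own cluster the clustered sandwich is the
    plain score-outer-product (heteroskedasticity-robust) sandwich with the
    G/(G-1) factor."""
    ds, _ = study_dataset
    model = lc.LatentClassModel.from_dataset(ds, 2)
    fit = model.fit(n_starts=10, seed=6, se_method=None)
    fit.estimate_ses(method="sandwich", groups=np.arange(ds.n))
    se_singleton = fit.se_item_probs.copy()

    # independent assembly: bread @ (n/(n-1) * S'S) @ bread
    param = _Parameterization(fit.class_weights, fit.item_probs)
    theta = param.pack(fit.class_weights, fit.item_probs)
    S = param.score_matrix(model._patterns, theta)[model._inverse]
    bread = np.linalg.inv(-param.hessian(model._patterns, model._weights,
                                         theta))
    cov = bread @ ((ds.n / (ds.n - 1)) * S.T @ S) @ bread
    from latclass.lca import _delta_method_ses
    _, se_manual, _ = _delta_method_ses(param, cov, fit.class_weights,
                                        fit.item_probs)
    np.testing.assert_allclose(se_singleton, se_manual, atol=1e-10)


def test_observed_info_ses_track_sampling_spread(ref_model):
    """Analytic SEs at N=2000 agree with the spread over replicates."""
    fits = []
    for rep in range(15):
        ds, _ = lc.sample_indicators(ref_model, 2000, seed=300 + rep)
        fits.append(lc.LatentClassModel.from_dataset(ds, 2).fit(
            n_starts=6, seed=rep, se_method=None))
    est = np.array([f.item_probs[0, 0, 0] for f in fits])   # men_dry agree c1
    fits[0].estimate_ses()
    se = fits[0].se_item_probs[0, 0, 0]
    assert 0.3 * se < est.std(ddof=1) < 3.0 * se


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------

def test_gof_zero_for_deterministic_model():
    rho = np.zeros((2, 2, 3))
    rho[:, 0, 0] = 1.0
    rho[:, 1, 1] = 1.0
    resp = np.array([[0, 0]] * 6 + [[1, 1]] * 4, dtype=np.int8)
    model = lc.LatentClassModel(resp, 2, n_categories=3)
    fit = model.fit(n_starts=5, seed=0, se_method=None)
    x2, _ = fit.pearson_gof(n_bootstrap=0)
    assert x2 == pytest.approx(0.0, abs=1e-5)


def test_gof_single_item_matches_classic_pearson():
    """J=1 is saturated: X2 is the one-way Pearson statistic against the
    mixture-implied category probabilities."""
    resp = np.array([0] * 50 + [1] * 30 + [2] * 20, dtype=np.int8)[:, None]
    model = lc.LatentClassModel(resp, 2, n_categories=3)
    fit = model.fit(n_starts=5, seed=1, se_method=None)
    x2, _ = fit.pearson_gof(n_bootstrap=0)
    implied = fit.class_weights @ fit.item_probs[0]
    obs = np.array([50, 30, 20])
    exp = 100 * implied
    classic = ((obs - exp) ** 2 / exp).sum() + 100 * max(0, 1 - implied.sum())
    assert x2 == pytest.approx(classic, abs=1e-8)


def test_gof_bootstrap_p_uniformish(ref_model):
    """Under the true model the bootstrap p-value is roughly uniform."""
    small = lc.GenerativeModel(pi=ref_model.pi, rho=ref_model.rho[:3],
                               indicator_ids=ref_model.indicator_ids[:3])
    pvals = []
    for rep in range(40):
        ds, _ = lc.sample_indicators(small, 150, seed=700 + rep)
        fit = lc.LatentClassModel.from_dataset(ds, 2).fit(
            n_starts=3, seed=rep, se_method=None)
        _, p = fit.pearson_gof(n_bootstrap=39, seed=rep, bootstrap_starts=2)
        pvals.append(p)
    pvals = np.array(pvals)
    assert 0.25 < pvals.mean() < 0.75
    assert (pvals < 0.05).mean() < 0.25


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def test_json_roundtrip(study_fit, tmp_path):
    path = tmp_path / "fit.json"
    study_fit.to_json(path)
    back = lc.LCAResults.from_json(path)
    np.testing.assert_allclose(back.class_weights, study_fit.class_weights)
    np.testing.assert_allclose(back.item_probs, study_fit.item_probs)
    np.testing.assert_allclose(back.se_item_probs, study_fit.se_item_probs)
    assert back.llf == study_fit.llf
    assert back.bic == study_fit.bic
    assert back.spec.n_classes == 2
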
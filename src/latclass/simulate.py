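"""Study-like synthetic data with a known latent truth.

The reference study deposited no individual-level data, but its printed
summary tables pin down most of a 2-class generative model: the class
weights, the modal class-conditional response probability of each final
indicator, and every indicator's observed 3-category marginal.
:func:`reconstruct_item_probs` completes the remaining conditional
probabilities from the mixture constraint

    marginal[c] = sum_k pi_k * rho[k, c]

and :func:`generate_survey` draws whole surveys — households, covariates,
latent classes with optional within-household concordance and a
class-exposure effect, indicator responses, item missingness — returning
the dataset together with the ground-truth labels that recovery tests need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from . import study
from .lca import LCAResults, _simulate_responses
from .survey import Codebook, Indicator, SurveyDataset, default_codebook

CAT_INDEX = {c: i for i, c in enumerate(study.CATEGORIES)}


class ReconstructionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# reconstruction of the printed generative model
# ---------------------------------------------------------------------------

def reconstruct_item_probs(marginals, printed, pi, clip_tol: float = 0.03):
    """Complete a 2-class, 3-category conditional row from printed values.

    Parameters
    ----------
    marginals : length-3 sequence
        Observed (agree, disagree, dont_know) proportions for the item.
    printed : {class index: (category label, probability)}
        The one printed conditional per class (the modal response).
    pi : length-2 class weights.
    clip_tol : float
        Largest tolerated constraint violation from printed rounding; the
        clipped mass and the residual marginal error may not exceed it.

    Returns
    -------
    rho : (2, 3) array, residual : float
        Completed conditionals (rows sum to 1, printed entries preserved)
        and the largest implied-marginal deviation.

    Notes
    -----
    A category with exactly one free class is solved directly from its
    mixture equation.  With the two printed conditionals in *different*
    categories this determines everything (one category then remains per
    class, absorbing the row's leftover mass).  With both printed values
    in the *same* category the system is rank-deficient by one: each
    class's leftover mass is then spread over the unresolved categories in
    proportion to their observed marginals, i.e. the two classes share the
    composition of the categories the printed table does not distinguish.
    Negative values arising from printed rounding are clipped to 0 and the
    free (non-printed) entries rescaled so each row sums to 1 — a printed
    boundary value (e.g. 1.00) therefore forces the rest of its row to 0.
    """
    m = np.asarray(marginals, dtype=float)
    m = m / m.sum()                       # absorb printed-rounding drift
    pi = np.asarray(pi, dtype=float)
    rho = np.full((2, 3), np.nan)
    fixed = np.zeros((2, 3), dtype=bool)
    for k, (cat, val, *_) in printed.items():
        c = CAT_INDEX[cat]
        rho[k, c] = val
        fixed[k, c] = True
    # categories where a single class is free: solve the mixture equation
    deferred = []
    for c in range(3):
        free_k = [k for k in range(2) if not fixed[k, c]]
        if len(free_k) == 1:
            k = free_k[0]
            other = 1 - k
            rho[k, c] = (m[c] - pi[other] * rho[other, c]) / pi[k]
        elif len(free_k) == 2:
            deferred.append(c)
    # leftover row mass spread over unresolved categories by their marginals
    if deferred:
        w = m[deferred]
        w = w / w.sum() if w.sum() > 0 else np.full(len(deferred), 1 / len(deferred))
        for k in range(2):
            leftover = 1.0 - np.nansum(rho[k])
            rho[k, deferred] = leftover * w
    clipped = float(-np.minimum(rho, 0).sum())
    if clipped > clip_tol:
        raise ReconstructionError(
            f"mixture constraints infeasible: clipped mass {clipped:.3f} "
            f"exceeds tolerance {clip_tol}")
    rho = np.maximum(rho, 0.0)
    # rescale the free entries so each row sums to 1, printed entries exact
    for k in range(2):
        target = 1.0 - rho[k, fixed[k]].sum()
        if target < -clip_tol:
            raise ReconstructionError("printed entries exceed unit mass")
        target = max(target, 0.0)
        current = rho[k, ~fixed[k]].sum()
        if current > 0:
            rho[k, ~fixed[k]] *= target / current
        else:
            rho[k, ~fixed[k]] = target / max(1, (~fixed[k]).sum())
    implied = pi @ rho
    residual = float(np.abs(implied - m).max())
    if residual > clip_tol:
        raise ReconstructionError(
            f"implied marginals deviate by {residual:.3f} > {clip_tol}")
    return rho, residual


# ---------------------------------------------------------------------------
# generative model
# ---------------------------------------------------------------------------

@dataclass
class GenerativeModel:
    """Known-truth data-generating process for a study-like survey.

    ``concordance`` is the standard deviation of a household-level normal
    random intercept on the class-1 log-odds (exchangeable within
    household); ``exposure_effect`` is the log-odds shift in class-1
    membership per unit of the binary basic-sanitation exposure (0 = the
    null structure of the reference study).
    """

    pi: np.ndarray
    rho: np.ndarray                       # J x 2 x 3
    indicator_ids: list[str]
    covariate_marginals: dict = field(
        default_factory=lambda: study.COVARIATE_MARGINALS)
    mean_household_size: float = study.MEAN_HOUSEHOLD_SIZE
    concordance: float = 0.3
    exposure_effect: float = 0.0
    missing_rate: float = 0.0
    reconstruction_residuals: dict | None = None

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if not np.allclose(self.pi.sum(), 1.0, atol=1e-8):
            raise ValueError("class weights must sum to 1")
        if not np.allclose(self.rho.sum(axis=2), 1.0, atol=1e-6):
            raise ValueError("conditional rows must sum to 1")
        if len(self.pi) != 2:
            raise ValueError("the generator implements the 2-class model")

    @property
    def codebook(self) -> Codebook:
        full = default_codebook()
        known = set(full.indicator_ids)
        inds = []
        for iid in self.indicator_ids:
            inds.append(full.indicator(iid) if iid in known else Indicator(iid))
        return Codebook(tuple(inds))


def reference_model(include_noise_indicators: bool = False,
                    concordance: float = 0.3,
                    exposure_effect: float = 0.0,
                    missing_rate: float = 0.0) -> GenerativeModel:
    """The generative model reconstructed from the printed study tables.

    Five informative indicators with conditionals completed by
    :func:`reconstruct_item_probs` under class weights (0.78, 0.22).  With
    ``include_noise_indicators`` the 11 pruned items are added as
    class-independent noise at their observed marginals (their true
    conditionals were never printed).
    """
    pi = np.asarray(study.CLASS_WEIGHTS, dtype=float)
    ids = list(study.FINAL_INDICATORS)
    rho_rows, residuals = [], {}
    for iid in ids:
        printed = {k: v[:2] for k, v in
                   study.FINAL_MODEL_CONDITIONALS[iid].items()}
        rho, res = reconstruct_item_probs(
            study.INDICATOR_MARGINALS[iid], printed, pi)
        rho_rows.append(rho)
        residuals[iid] = res
    if include_noise_indicators:
        for iid in study.INDICATOR_IDS:
            if iid in study.FINAL_INDICATORS:
                continue
            m = np.asarray(study.INDICATOR_MARGINALS[iid], dtype=float)
            m = m / m.sum()
            rho_rows.append(np.tile(m, (2, 1)))
            ids.append(iid)
    return GenerativeModel(pi=pi, rho=np.stack(rho_rows), indicator_ids=ids,
                           concordance=concordance,
                           exposure_effect=exposure_effect,
                           missing_rate=missing_rate,
                           reconstruction_residuals=residuals)


# ---------------------------------------------------------------------------
# survey generation
# ---------------------------------------------------------------------------

def _zt_poisson_lambda(mean: float) -> float:
    """Rate of a zero-truncated Poisson with the given mean."""
    if mean <= 1.0:
        raise ValueError("mean household size must exceed 1")
    return brentq(lambda lam: lam / (1 - np.exp(-lam)) - mean, 1e-6, 50.0)


def _draw_categorical(rng, marginals: dict, size: int) -> np.ndarray:
    cats = list(marginals)
    p = np.asarray([marginals[c] for c in cats], dtype=float)
    p = p / p.sum()
    return rng.choice(np.asarray(cats, dtype=object), size=size, p=p)


def generate_survey(model: GenerativeModel, n_households: int = 98,
                    seed: int | None = None):
    """Draw a full study-like survey.

    Household sizes are zero-truncated Poisson calibrated to the model's
    mean size; sanitation, walls and asset deprivation are drawn at the
    household level, the rest per individual.  Latent class follows a
    logistic model with the household random intercept (concordance) and
    the configured exposure effect; indicator responses are drawn from the
    class-conditional multinomials, then items are blanked MCAR at
    ``missing_rate``.

    Returns ``(SurveyDataset, true_labels)`` with labels 1-based
    (1 = class 0 = consistent use) aligned to dataset rows.
    """
    rng = np.random.default_rng(seed)
    lam = _zt_poisson_lambda(model.mean_household_size)
    sizes = []
    for _ in range(n_households):
        s = 0
        while s == 0:
            s = rng.poisson(lam)
        sizes.append(s)
    sizes = np.asarray(sizes)
    n = int(sizes.sum())
    hh_index = np.repeat(np.arange(n_households), sizes)
    household_id = np.array([f"hh{h:04d}" for h in hh_index], dtype=object)
    individual_id = np.array([f"ind{i:05d}" for i in range(n)], dtype=object)

    cm = model.covariate_marginals
    hh_sanitation = _draw_categorical(rng, cm["sanitation"], n_households)
    hh_walls = _draw_categorical(rng, cm["cement_walls"], n_households)
    hh_asset = _draw_categorical(rng, cm["asset_deprived"], n_households)
    covariates = pd.DataFrame({
        "age": np.round(study.AGE_MIN + rng.exponential(
            (study.AGE_MEDIAN - study.AGE_MIN) / np.log(2), size=n)),
        "sex": _draw_categorical(rng, cm["sex"], n),
        "ethnicity": _draw_categorical(rng, cm["ethnicity"], n),
        "education": _draw_categorical(rng, cm["education"], n),
        "payment_type": _draw_categorical(rng, cm["payment_type"], n),
        "cement_walls": hh_walls[hh_index],
        "asset_deprived": hh_asset[hh_index],
        "sanitation": hh_sanitation[hh_index],
    })

    base = logit(model.pi[0])
    b_h = rng.normal(0.0, model.concordance, size=n_households)
    basic = (hh_sanitation[hh_index] == "basic").astype(float)
    p1 = expit(base + b_h[hh_index] + model.exposure_effect * basic)
    labels = np.where(rng.random(n) < p1, 1, 2)      # 1-based

    J = len(model.indicator_ids)
    responses = np.empty((n, J), dtype=np.int8)
    u = rng.random((n, J))
    for k in range(2):
        mask = labels == k + 1
        if mask.any():
            cum = np.cumsum(model.rho[:, k, :], axis=1)
            cum = cum / cum[:, -1:]
            responses[mask] = (u[mask, :, None] > cum[None, :, :]).sum(axis=2)
    if model.missing_rate > 0:
        blank = rng.random((n, J)) < model.missing_rate
        responses[blank] = -1

    dataset = SurveyDataset(
        individual_id=individual_id, household_id=household_id,
        responses=responses, codebook=model.codebook, covariates=covariates)
    return dataset, labels


def sample_indicators(model: GenerativeModel, n: int,
                      seed: int | None = None):
    """Indicator responses only, for measurement-model experiments.

    Draws exactly ``n`` individuals from (pi, rho) with no household or
    covariate structure.  Returns ``(SurveyDataset, labels)``.
    """
    rng = np.random.default_rng(seed)
    labels = rng.choice(2, size=n, p=model.pi) + 1
    J = len(model.indicator_ids)
    responses = np.empty((n, J), dtype=np.int8)
    u = rng.random((n, J))
    for k in range(2):
        mask = labels == k + 1
        if mask.any():
            cum = np.cumsum(model.rho[:, k, :], axis=1)
            cum = cum / cum[:, -1:]
            responses[mask] = (u[mask, :, None] > cum[None, :, :]).sum(axis=2)
    ids = np.array([f"ind{i:05d}" for i in range(n)], dtype=object)
    dataset = SurveyDataset(individual_id=ids, household_id=ids.copy(),
                            responses=responses, codebook=model.codebook)
    return dataset, labels


def generate_from_fit(fit: LCAResults, n: int,
                      seed: int | None = None) -> SurveyDataset:
    """Parametric-bootstrap dataset from a fitted model (indicators only)."""
    rng = np.random.default_rng(seed)
    ids = np.array([f"boot{i:05d}" for i in range(n)], dtype=object)
    if n == 0:
        responses = np.empty((0, fit.item_probs.shape[0]), dtype=np.int8)
    else:
        responses = _simulate_responses(fit.class_weights, fit.item_probs,
                                        n, rng)
    codebook = Codebook(tuple(Indicator(i) for i in fit.indicator_ids))
    return SurveyDataset(individual_id=ids, household_id=ids.copy(),
                         responses=responses, codebook=codebook)
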
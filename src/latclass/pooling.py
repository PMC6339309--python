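"""Pseudo-class multiple imputation and Rubin-pooled structural regression.

Latent class assignment is uncertain; treating the modal class as known
understates the variance of any downstream regression.  The pseudo-class
approach draws M (default 5) class memberships per individual from their
posterior, fits the structural logistic regression once per draw with
household-clustered sandwich standard errors, and combines the M estimates
with Rubin's rules (between/within variance decomposition, Barnard-Rubin
degrees of freedom).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .lca import LCAResults
from .survey import SurveyDataset, binarize_sanitation


class SeparationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# pseudo-class draws
# ---------------------------------------------------------------------------

@dataclass
class PseudoClassDraws:
    """N x M imputed class labels (1-based) drawn from the posteriors."""

    draws: np.ndarray
    seed: int | None = None
    tie_flags: np.ndarray = field(init=False)
    modal: np.ndarray = field(init=False)

    def __post_init__(self):
        self.draws = np.asarray(self.draws, dtype=int)
        if self.draws.ndim != 2:
            raise ValueError("draws must be N x M")
        if self.draws.min() < 1:
            raise ValueError("labels are 1-based")
        self.modal, self.tie_flags = _modal(self.draws)

    @property
    def n_imputations(self) -> int:
        return self.draws.shape[1]


def _modal(draws: np.ndarray):
    n, _ = draws.shape
    kmax = draws.max()
    modal = np.empty(n, dtype=int)
    ties = np.zeros(n, dtype=bool)
    for i in range(n):
        counts = np.bincount(draws[i], minlength=kmax + 1)[1:]
        top = counts.max()
        winners = np.flatnonzero(counts == top) + 1
        modal[i] = winners[0]          # tie -> lower label
        ties[i] = len(winners) > 1
    return modal, ties


def draw_pseudo_classes(tau: np.ndarray, n_imputations: int = 5,
                        seed: int | None = None) -> PseudoClassDraws:
    """Draw class labels from each individual's posterior.

    For each individual i and imputation m an independent Uniform(0,1) is
    compared with the cumulative posterior; the label is the smallest class
    whose cumulative probability reaches the draw.  Fully reproducible from
    ``seed``.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(np.abs(tau.sum(axis=1) - 1.0) > 1e-8):
        raise ValueError("posterior rows must sum to 1")
    if n_imputations < 1:
        raise ValueError("need at least one imputation")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(tau, axis=1)
    cum[:, -1] = 1.0
    u = rng.random((tau.shape[0], n_imputations))
    labels = (u[:, :, None] > cum[:, None, :]).sum(axis=2) + 1
    return PseudoClassDraws(draws=labels, seed=seed)


def modal_membership(draws: PseudoClassDraws) -> np.ndarray:
    """Most frequent label per individual (ties go to the lower label)."""
    return draws.modal


def class_by_demographics(labels: np.ndarray, dataset: SurveyDataset,
                          target_class: int = 1) -> pd.DataFrame:
    """Per-stratum proportion assigned to ``target_class`` with binomial SE.

    Mirrors the published demographic breakdown: age is banded
    (13-17, 18-21, 22-26, 27-36, 37+), categorical covariates are stratified
    by code (missing excluded from strata).  SE = sqrt(p(1-p)/n); empty
    strata report n=0 and an undefined proportion.
    """
    labels = np.asarray(labels)
    if len(labels) != dataset.n:
        raise ValueError("labels not aligned with dataset")
    in_class = (labels == target_class).astype(float)
    rows = [{"variable": "overall", "stratum": "all",
             **_prop_se(in_class)}]
    cov = dataset.covariates
    if "age" in cov.columns:
        age = pd.to_numeric(cov["age"], errors="coerce")
        bands = [(13, 18, "13-17"), (18, 22, "18-21"), (22, 27, "22-26"),
                 (27, 37, "27-36"), (37, np.inf, "37+")]
        for lo, hi, name in bands:
            mask = (age >= lo) & (age < hi)
            rows.append({"variable": "age", "stratum": name,
                         **_prop_se(in_class[mask.to_numpy()])})
    for var in ["sex", "ethnicity", "education", "payment_type",
                "cement_walls", "asset_deprived", "sanitation"]:
        if var not in cov.columns:
            continue
        vals = cov[var].astype(str)
        for cat in [c for c in vals.unique() if c != "missing"]:
            mask = (vals == cat).to_numpy()
            rows.append({"variable": var, "stratum": cat,
                         **_prop_se(in_class[mask])})
    return pd.DataFrame(rows)


def _prop_se(x: np.ndarray) -> dict:
    n = len(x)
    if n == 0:
        return {"proportion": np.nan, "se": np.nan, "n": 0}
    p = float(np.mean(x))
    return {"proportion": p, "se": float(np.sqrt(p * (1 - p) / n)), "n": n}


# ---------------------------------------------------------------------------
# cluster-robust logistic regression
# ---------------------------------------------------------------------------

@dataclass
class ClusterLogitFit:
    """One logistic fit with household-clustered sandwich covariance."""

    params: pd.Series
    cov: pd.DataFrame
    n_obs: int
    n_clusters: int
    n_dropped: int
    outcome_coding: str = "class1=1"

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)


def fit_cluster_logit(outcome, design: pd.DataFrame, clusters,
                      add_constant: bool = True,
                      separation_bound: float = 15.0) -> ClusterLogitFit:
    """ML logistic regression with cluster-aggregated sandwich covariance.

    Rows with a missing outcome or any missing design cell are dropped
    (complete-case, with the dropped count recorded).  The covariance is
    the clustered sandwich with the G/(G-1) small-sample factor; with
    singleton clusters it degenerates to the heteroskedasticity-robust
    estimator (up to that factor).  Coefficients larger than
    ``separation_bound`` in absolute value raise a :class:`SeparationError`
    naming the covariate.
    """
    y = pd.Series(np.asarray(outcome, dtype=float)).reset_index(drop=True)
    X = design.reset_index(drop=True).astype(float)
    g = pd.Series(np.asarray(clusters, dtype=object)).reset_index(drop=True)
    if add_constant:
        X = sm.add_constant(X, has_constant="add")
    keep = y.notna() & X.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    y, X, g = y[keep], X[keep], g[keep]
    n_clusters = g.nunique()
    if n_clusters < 2:
        raise ValueError("clustered standard errors need >= 2 clusters")
    model = sm.Logit(y.to_numpy(), X.to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = model.fit(disp=0, maxiter=200)
        except (PerfectSeparationWarning, PerfectSeparationError,
                np.linalg.LinAlgError) as exc:
            raise SeparationError(
                f"(quasi-)separation detected; design columns "
                f"{list(X.columns)}") from exc
    params = pd.Series(res.params, index=X.columns)
    big = params.abs() > separation_bound
    if big.any():
        raise SeparationError(
            f"(quasi-)separation detected for covariate(s) "
            f"{list(params.index[big])}")
    # clustered sandwich: bread = inverse observed information, meat =
    # household score sums with the G/(G-1) small-sample factor
    bread = np.asarray(res.cov_params())
    scores = (y.to_numpy() - res.predict())[:, None] * X.to_numpy()
    _, inv = np.unique(g.to_numpy(), return_inverse=True)
    Sg = np.zeros((n_clusters, X.shape[1]))
    np.add.at(Sg, inv, scores)
    meat = (n_clusters / (n_clusters - 1)) * (Sg.T @ Sg)
    cov = pd.DataFrame(bread @ meat @ bread, index=X.columns,
                       columns=X.columns)
    return ClusterLogitFit(params=params, cov=cov, n_obs=int(keep.sum()),
                           n_clusters=int(n_clusters), n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------

@dataclass
class PooledResult:
    """Rubin-combined coefficients with the variance decomposition.

    Per coefficient: pooled estimate Qbar (mean over the M fits),
    within-imputation variance W, between-imputation variance B, total
    variance T = W + (1 + 1/M) B, Barnard-Rubin degrees of freedom, and the
    odds ratio with a t-based 95% CI computed on the log-odds scale.
    """

    table: pd.DataFrame
    n_imputations: int

    def summary(self) -> str:
        lines = [f"Rubin-pooled logistic regression (M = {self.n_imputations})",
                 "=" * 72]
        hdr = (f"{'term':<22}{'coef':>8}{'se':>8}{'OR':>7}"
               f"{'2.5%':>8}{'97.5%':>8}{'df':>9}")
        lines.append(hdr)
        for term, r in self.table.iterrows():
            df = r['df']
            lines.append(
                f"{term:<22}{r['coef']:>8.3f}{r['se']:>8.3f}{r['or']:>7.2f}"
                f"{r['or_ci_low']:>8.2f}{r['or_ci_high']:>8.2f}"
                + (f"{df:>9.1f}" if np.isfinite(df) else f"{'inf':>9}"))
        return "\n".join(lines)


def pool_rubin(fits: list[ClusterLogitFit]) -> PooledResult:
    """Combine M cluster-robust logistic fits by Rubin's rules."""
    if len(fits) < 2:
        raise ValueError("pooling needs M >= 2 fits")
    index = fits[0].params.index
    for f in fits[1:]:
        if not f.params.index.equals(index):
            raise ValueError("imputation fits have mismatched coefficients")
    M = len(fits)
    Q = np.stack([f.params.to_numpy() for f in fits])      # M x p
    U = np.stack([np.diag(f.cov.to_numpy()) for f in fits])
    qbar = Q.mean(axis=0)
    wbar = U.mean(axis=0)
    B = Q.var(axis=0, ddof=1)
    T = wbar + (1 + 1 / M) * B
    nu_com = max(1, min(f.n_obs for f in fits) - len(index))
    rows = []
    for i, term in enumerate(index):
        if B[i] <= 0 or T[i] <= 0:
            df = np.inf
        else:
            lam = (1 + 1 / M) * B[i] / T[i]
            df_old = (M - 1) / lam ** 2
            df_obs = ((nu_com + 1) / (nu_com + 3)) * nu_com * (1 - lam)
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
        tq = stats.norm.ppf(0.975) if not np.isfinite(df) else stats.t.ppf(0.975, df)
        se = np.sqrt(T[i])
        rows.append({
            "coef": qbar[i], "se": se, "within_var": wbar[i],
            "between_var": B[i], "total_var": T[i], "df": df,
            "or": np.exp(qbar[i]),
            "or_ci_low": np.exp(qbar[i] - tq * se),
            "or_ci_high": np.exp(qbar[i] + tq * se),
        })
    return PooledResult(table=pd.DataFrame(rows, index=index),
                        n_imputations=M)


# ---------------------------------------------------------------------------
# structural pipeline
# ---------------------------------------------------------------------------

def _design_matrices(dataset: SurveyDataset, adjusted: bool):
    """Design with the published referent coding.

    Referents: less-than-basic sanitation, less-than-primary education,
    Chachi/Mestizo/Other ethnicity, male, non-cement walls, asset-deprived
    household.  Missing covariate codes become NaN (complete-case later).
    """
    cov = dataset.covariates
    X = pd.DataFrame({"basic_sanitation": binarize_sanitation(dataset)})
    if adjusted:
        edu = cov["education"].astype(str)
        for cat, name in [("primary", "edu_primary"),
                          ("less_than_secondary", "edu_less_than_secondary"),
                          ("secondary", "edu_secondary")]:
            col = (edu == cat).astype(float)
            col[edu == "missing"] = np.nan
            X[name] = col
        X["afro_ecuadorian"] = (cov["ethnicity"].astype(str)
                                == "afro_ecuadorian").astype(float)
        X["female"] = (cov["sex"].astype(str) == "female").astype(float)
        walls = cov["cement_walls"].astype(str)
        wall = (walls == "yes").astype(float)
        wall[walls == "missing"] = np.nan
        X["cement_walls"] = wall
        asset = cov["asset_deprived"].astype(str)
        nondep = (asset == "no").astype(float)
        nondep[asset == "missing"] = np.nan
        X["non_asset_deprived"] = nondep
    return X


@dataclass
class StructuralResult:
    pooled: PooledResult
    per_imputation: list[ClusterLogitFit]
    draws: PseudoClassDraws


def run_structural_pipeline(fit: LCAResults, dataset: SurveyDataset,
                            n_imputations: int = 5, seed: int | None = None,
                            models: tuple = ("unadjusted", "adjusted"),
                            target_class: int = 1
                            ) -> dict[str, StructuralResult]:
    """Posterior -> pseudo-class draws -> M cluster-robust logits -> pooling.

    The outcome of each regression is membership in ``target_class``
    (class 1 = consistent latrine use = 1), imputed independently per draw;
    sanitation access is the exposure.  Returns the unadjusted and the
    covariate-adjusted pooled models.
    """
    if fit.posteriors.shape[0] != dataset.n:
        raise ValueError("fit and dataset are not aligned")
    draws = draw_pseudo_classes(fit.posteriors, n_imputations, seed=seed)
    out: dict[str, StructuralResult] = {}
    for name in models:
        X = _design_matrices(dataset, adjusted=(name == "adjusted"))
        fits = []
        for m in range(n_imputations):
            y = (draws.draws[:, m] == target_class).astype(float)
            fits.append(fit_cluster_logit(y, X, dataset.household_id))
        out[name] = StructuralResult(pooled=pool_rubin(fits),
                                     per_imputation=fits, draws=draws)
    return out


def structural_table(results: dict[str, StructuralResult]) -> pd.DataFrame:
    """Long-format OR table across the fitted model variants."""
    rows = []
    for name, res in results.items():
        for term, r in res.pooled.table.iterrows():
            rows.append({"model": name, "term": term, "or": r["or"],
                         "or_ci_low": r["or_ci_low"],
                         "or_ci_high": r["or_ci_high"],
                         "coef": r["coef"], "se": r["se"]})
    return pd.DataFrame(rows)
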
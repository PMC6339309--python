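"""Model selection and indicator diagnostics.

Covers choosing the number of latent classes (BIC with interpretability
guards and a relative-entropy floor), pruning indicators whose
class-conditional response profiles are statistically indistinguishable
(the CI-overlap rule), checking mixture-implied against observed marginals,
and the two-step polychoric correlation used to screen indicator pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .lca import LCAResults, LCASpec, fit_lca
from .survey import MISSING_CODE, SurveyDataset


class NoAcceptableModelError(RuntimeError):
    def __init__(self, msg, table=None):
        super().__init__(msg)
        self.table = table


@dataclass
class FitComparison:
    """One row per candidate K plus the decision record."""

    table: pd.DataFrame
    fits: dict
    selected_k: int
    decision: str


def compare_class_solutions(dataset: SurveyDataset, k_list, spec: LCASpec,
                            min_class_n: int = 10, entropy_floor: float = 0.80,
                            delta_bic: float = 2.0, gof_bootstrap: int = 0,
                            ) -> FitComparison:
    """Fit each candidate K and choose a class solution.

    Rule: prefer the lowest BIC, but reject any solution containing a class
    whose expected count ``N * pi_k`` falls below ``min_class_n`` — a class
    of a handful of people cannot be carried into multivariable analysis.
    Near-BIC-ties (within ``delta_bic``) go to the smaller K.  Solutions
    with relative entropy below ``entropy_floor`` are flagged; if no
    candidate is acceptable a :class:`NoAcceptableModelError` carries the
    comparison table.
    """
    rows, fits = [], {}
    n = dataset.n
    for i, k in enumerate(k_list):
        kspec = LCASpec(n_classes=int(k), indicator_ids=spec.indicator_ids,
                        n_starts=spec.n_starts, max_iter=spec.max_iter,
                        tol=spec.tol,
                        seed=None if spec.seed is None else spec.seed + i,
                        se_method=None)
        fit = fit_lca(dataset, kspec)
        x2, pval = fit.pearson_gof(n_bootstrap=gof_bootstrap,
                                   seed=kspec.seed) if gof_bootstrap else (
            fit.pearson_gof(n_bootstrap=0)[0], np.nan)
        min_count = float(n * fit.class_weights.min())
        rows.append({
            "n_classes": int(k), "bic": fit.bic, "x2": x2,
            "bootstrap_p": pval, "rel_entropy": fit.rel_entropy,
            "class_weights": tuple(np.round(fit.class_weights, 4)),
            "min_expected_count": min_count,
            "acceptable": min_count >= min_class_n,
            "entropy_ok": fit.rel_entropy >= entropy_floor,
        })
        fits[int(k)] = fit
    table = pd.DataFrame(rows).set_index("n_classes")
    ok = table[table["acceptable"] & table["entropy_ok"]]
    if ok.empty:
        raise NoAcceptableModelError(
            "no candidate class solution passes the interpretability and "
            "entropy guards", table=table)
    best_bic = ok["bic"].min()
    near = ok[ok["bic"] <= best_bic + delta_bic]
    selected = int(near.index.min())
    if len(near) > 1:
        decision = (f"BIC near-tie (<{delta_bic}) among K={list(near.index)}; "
                    f"chose the most parsimonious acceptable K={selected}")
    else:
        decision = f"lowest BIC among acceptable candidates: K={selected}"
    rejected = table.index[~table["acceptable"]].tolist()
    if rejected:
        decision += (f"; rejected K={rejected} for a class with expected "
                     f"count < {min_class_n}")
    return FitComparison(table=table, fits=fits, selected_k=selected,
                         decision=decision)


@dataclass
class PruneResult:
    """Verdicts of the CI-overlap rule, with the interval evidence."""

    retained: list
    removed: list
    evidence: pd.DataFrame   # per (indicator, category): CIs and verdict

    def __post_init__(self):
        assert not set(self.retained) & set(self.removed)


def prune_uninformative(fit: LCAResults, alpha: float = 0.05,
                        z: float | None = None) -> PruneResult:
    """Drop indicators whose item-probability CIs overlap between classes.

    For each indicator and response category, build Wald CIs
    ``rho +/- z * SE`` (truncated to [0, 1]) in each of the two classes; the
    indicator is informative — retained — iff at least one category's
    intervals are disjoint.  A boundary estimate has Wald SE 0, which would
    make its interval a point; a zero-width interval from a zero cell count
    is an artifact, so boundary cells get a one-sided rule-of-three width
    (3 / expected class count) on their open side.  A boundary estimate of
    1.00 therefore stays decisively separable from any interval bounded
    away from 1.  The rule as printed is pairwise, so only K=2 is
    supported.  Verdicts come from a single pass over one fit
    (order-independent).
    """
    if fit.n_classes != 2:
        raise ValueError("the CI-overlap pruning rule is defined for K=2")
    if fit.se_item_probs is None:
        raise ValueError("fit has no standard errors; run estimate_ses first")
    if z is None:
        z = float(stats.norm.ppf(1 - alpha / 2))
    rho, se = fit.item_probs, fit.se_item_probs
    J, _, C = rho.shape
    ids = fit.indicator_ids
    # effective per-class sample size for rule-of-three boundary widths
    class_n = np.maximum(fit.posteriors.sum(axis=0), 1.0)
    rows = []
    retained, removed = [], []
    for j in range(J):
        informative = False
        for c in range(C):
            lo = np.clip(rho[j, :, c] - z * se[j, :, c], 0.0, 1.0)
            hi = np.clip(rho[j, :, c] + z * se[j, :, c], 0.0, 1.0)
            for k in range(2):
                if se[j, k, c] == 0.0:
                    if rho[j, k, c] <= 0.5:
                        hi[k] = min(1.0, rho[j, k, c] + 3.0 / class_n[k])
                    else:
                        lo[k] = max(0.0, rho[j, k, c] - 3.0 / class_n[k])
            disjoint = bool(lo[0] > hi[1] or lo[1] > hi[0])
            informative = informative or disjoint
            rows.append({
                "indicator": ids[j], "category": c,
                "class1_lo": lo[0], "class1_hi": hi[0],
                "class2_lo": lo[1], "class2_hi": hi[1],
                "disjoint": disjoint,
            })
        (retained if informative else removed).append(ids[j])
    return PruneResult(retained=retained, removed=removed,
                       evidence=pd.DataFrame(rows))


def refit_pruned(dataset: SurveyDataset, prune: PruneResult,
                 spec: LCASpec) -> LCAResults:
    """One refit on the retained indicators (single-pass reduction)."""
    if not prune.retained:
        raise ValueError("no indicators retained")
    new_spec = LCASpec(n_classes=spec.n_classes,
                       indicator_ids=list(prune.retained),
                       n_starts=spec.n_starts, max_iter=spec.max_iter,
                       tol=spec.tol, seed=spec.seed, se_method=spec.se_method)
    return fit_lca(dataset, new_spec)


def mixture_marginal_check(fit: LCAResults,
                           dataset: SurveyDataset | None = None
                           ) -> pd.DataFrame:
    """Mixture-implied vs observed per-category marginals.

    The implied marginal for (item j, category c) is
    ``sum_k pi_k * rho[j, k, c]``; its deviation from the observed category
    proportion is a basic internal-consistency diagnostic (it shrinks to 0
    in N when the data come from the fitted family).
    """
    pi, rho = fit.class_weights, fit.item_probs
    implied = np.einsum("k,jkc->jc", pi, rho)
    J, C = implied.shape
    ids = fit.indicator_ids
    observed = np.full((J, C), np.nan)
    if dataset is None and fit.model is not None:
        responses = fit.model.responses
    elif dataset is not None:
        responses = dataset.select_indicators(ids).responses
    else:
        responses = None
    if responses is not None:
        for j in range(J):
            col = responses[:, j]
            obs = col[col != MISSING_CODE]
            if len(obs):
                observed[j] = np.bincount(obs, minlength=C) / len(obs)
    rows = []
    for j in range(J):
        for c in range(C):
            rows.append({
                "indicator": ids[j], "category": c,
                "implied": implied[j, c], "observed": observed[j, c],
                "abs_dev": abs(implied[j, c] - observed[j, c]),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# polychoric correlation (two-step estimator)
# ---------------------------------------------------------------------------

@dataclass
class PolychoricResult:
    rho: float
    thresholds_x: np.ndarray
    thresholds_y: np.ndarray
    boundary: bool


def _thresholds(v: np.ndarray, n_cats: int) -> np.ndarray:
    cum = np.cumsum(np.bincount(v, minlength=n_cats))[:-1] / len(v)
    return stats.norm.ppf(cum)


def _bvn_rect(lo1, hi1, lo2, hi2, r):
    """P(lo1 < X <= hi1, lo2 < Y <= hi2) for standard bivariate normal."""
    cov = np.array([[1.0, r], [r, 1.0]])
    mvn = stats.multivariate_normal(mean=[0, 0], cov=cov, allow_singular=True)

    def F(a, b):
        if a == -np.inf or b == -np.inf:
            return 0.0
        if a == np.inf and b == np.inf:
            return 1.0
        if a == np.inf:
            return float(stats.norm.cdf(b))
        if b == np.inf:
            return float(stats.norm.cdf(a))
        return float(mvn.cdf([a, b]))

    return F(hi1, hi2) - F(lo1, hi2) - F(hi1, lo2) + F(lo1, lo2)


def polychoric_correlation(x, y, bound: float = 0.999) -> PolychoricResult:
    """Two-step polychoric correlation between two ordinal variables.

    Step 1 fixes the thresholds at inverse-normal transforms of the
    cumulative marginals; step 2 maximizes the bivariate-normal cell
    likelihood over the correlation in (-bound, bound).  Estimates pinned
    at the bound (e.g. y identical to x) are flagged as boundary.
    """
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    if x.shape != y.shape:
        raise ValueError("x and y must share N")
    keep = (x != MISSING_CODE) & (y != MISSING_CODE)
    x, y = x[keep], y[keep]
    cx, cy = x.max() + 1, y.max() + 1
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        raise ValueError("polychoric correlation undefined: a variable has "
                         "a single observed category")
    tx = _thresholds(x, cx)
    ty = _thresholds(y, cy)
    counts = np.zeros((cx, cy))
    np.add.at(counts, (x, y), 1.0)
    ex = np.concatenate([[-np.inf], tx, [np.inf]])
    ey = np.concatenate([[-np.inf], ty, [np.inf]])

    def negloglik(r):
        ll = 0.0
        for a in range(cx):
            for b in range(cy):
                if counts[a, b] == 0:
                    continue
                p = _bvn_rect(ex[a], ex[a + 1], ey[b], ey[b + 1], r)
                ll += counts[a, b] * np.log(max(p, 1e-300))
        return -ll

    res = optimize.minimize_scalar(negloglik, bounds=(-bound, bound),
                                   method="bounded",
                                   options={"xatol": 1e-6})
    rho = float(res.x)
    boundary = abs(rho) >= bound - 1e-4
    return PolychoricResult(rho=rho, thresholds_x=tx, thresholds_y=ty,
                            boundary=boundary)


def polychoric_matrix(dataset: SurveyDataset) -> pd.DataFrame:
    """Pairwise polychoric correlations between all indicators."""
    ids = dataset.codebook.indicator_ids
    J = len(ids)
    M = np.eye(J)
    for a in range(J):
        for b in range(a + 1, J):
            try:
                r = polychoric_correlation(dataset.responses[:, a],
                                           dataset.responses[:, b]).rho
            except ValueError:
                r = np.nan
            M[a, b] = M[b, a] = r
    return pd.DataFrame(M, index=ids, columns=ids)
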
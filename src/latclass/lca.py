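"""Latent class analysis for polytomous survey indicators.

The measurement model is a finite mixture of independent multinomials:
an individual belongs to one of K unobserved classes with prevalence
``pi_k``; given class k, item j takes category c with probability
``rho[j, k, c]`` independently across items.  Individuals with partially
missing items contribute the likelihood of their observed items only
(full-information maximum likelihood under MAR), so

    L_i = sum_k pi_k * prod_{j in obs(i)} rho[j, k, y_ij].

Estimation is EM with random restarts; identical response patterns are
collapsed to weighted patterns, which makes large-N fits cheap.  Standard
errors come from the observed information matrix in an unconstrained
(multinomial-logit) parameterization, with an optional household-clustered
sandwich variant.

The public surface follows the statsmodels convention:
``LatentClassModel(...).fit()`` returns an :class:`LCAResults`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .survey import MISSING_CODE, SurveyDataset

RHO_FLOOR = 1e-10      # floor inside E-step logs only; reported rho may be 0
BOUNDARY_EPS = 1e-6    # rho within this of {0,1} is treated as a boundary


class ConvergenceError(RuntimeError):
    """No EM restart converged; carries the per-restart log-likelihoods."""

    def __init__(self, msg: str, start_logliks=None):
        super().__init__(msg)
        self.start_logliks = start_logliks


class IdentifiabilityError(ValueError):
    pass


class SingularInformationError(RuntimeError):
    """The observed information matrix is (numerically) singular."""


# ---------------------------------------------------------------------------
# low-level likelihood machinery on collapsed response patterns
# ---------------------------------------------------------------------------

def _collapse(responses: np.ndarray):
    """Group identical response rows -> (patterns, weights, inverse)."""
    patterns, inverse, counts = np.unique(
        responses, axis=0, return_inverse=True, return_counts=True)
    return patterns.astype(np.int8), counts.astype(float), inverse


def _pattern_logf(patterns, rho):
    """R x K matrix of per-class log response-vector probabilities."""
    R, J = patterns.shape
    K = rho.shape[1]
    logrho = np.log(np.maximum(rho, RHO_FLOOR))
    logf = np.zeros((R, K))
    for j in range(J):
        y = patterns[:, j]
        mask = y != MISSING_CODE
        if mask.any():
            logf[mask] += logrho[j][:, y[mask]].T
    return logf


def _e_step(patterns, weights, pi, rho):
    logf = _pattern_logf(patterns, rho)
    lw = logf + np.log(np.maximum(pi, RHO_FLOOR))[None, :]
    m = logsumexp(lw, axis=1)
    ll = float(weights @ m)
    tau = np.exp(lw - m[:, None])
    return ll, tau


def _m_step(patterns, weights, tau, n_categories):
    J = patterns.shape[1]
    K = tau.shape[1]
    wt = tau * weights[:, None]
    pi = wt.sum(axis=0) / weights.sum()
    rho = np.zeros((J, K, n_categories))
    for j in range(J):
        y = patterns[:, j]
        mask = y != MISSING_CODE
        num = np.zeros((n_categories, K))
        np.add.at(num, y[mask], wt[mask])
        denom = wt[mask].sum(axis=0)
        denom = np.where(denom > 0, denom, 1.0)
        rho[j] = (num / denom[None, :]).T
    return pi, rho


def _em_single(patterns, weights, n_categories, K, pi0, rho0, tol, max_iter):
    pi, rho = pi0, rho0
    ll_old = -np.inf
    history = []
    converged = False
    for _ in range(max_iter):
        ll, tau = _e_step(patterns, weights, pi, rho)
        history.append(ll)
        if ll - ll_old < tol and np.isfinite(ll_old):
            converged = True
            break
        ll_old = ll
        pi, rho = _m_step(patterns, weights, tau, n_categories)
    else:
        ll, tau = _e_step(patterns, weights, pi, rho)
        history.append(ll)
    return pi, rho, tau, ll, converged, history


def _sort_classes(pi, rho, tau):
    """Relabel classes by descending prevalence (class 0 = largest)."""
    order = np.argsort(-pi, kind="stable")
    return pi[order], rho[:, order, :], tau[:, order]


# ---------------------------------------------------------------------------
# unconstrained parameterization for standard errors
# ---------------------------------------------------------------------------

class _Parameterization:
    """Multinomial-logit coordinates for the interior (non-boundary) cells.

    pi is softmax over classes with class 0 as reference.  Each rho row
    (j, k) is softmax over its *active* categories (rho > BOUNDARY_EPS)
    with the first active category as reference; boundary categories stay
    pinned at 0/1 and get SE 0.
    """

    def __init__(self, pi, rho):
        self.K = len(pi)
        self.J, _, self.C = rho.shape
        self.active = [
            [c for c in range(self.C) if rho[j, k, c] > BOUNDARY_EPS]
            for j in range(self.J) for k in range(self.K)
        ]
        self.names: list[tuple] = []
        if self.K > 1:
            self.names += [("pi", k) for k in range(1, self.K)]
        for j in range(self.J):
            for k in range(self.K):
                act = self.active[j * self.K + k]
                self.names += [("rho", j, k, c) for c in act[1:]]
        self.n_free = len(self.names)

    def pack(self, pi, rho):
        theta = []
        if self.K > 1:
            ref = max(pi[0], BOUNDARY_EPS)
            theta += [np.log(max(pi[k], BOUNDARY_EPS) / ref)
                      for k in range(1, self.K)]
        for j in range(self.J):
            for k in range(self.K):
                act = self.active[j * self.K + k]
                if len(act) > 1:
                    ref = rho[j, k, act[0]]
                    theta += [np.log(rho[j, k, c] / ref) for c in act[1:]]
        return np.array(theta)

    def unpack(self, theta):
        pos = 0
        pi = np.ones(self.K)
        if self.K > 1:
            z = np.concatenate([[0.0], theta[pos:pos + self.K - 1]])
            pos += self.K - 1
            pi = np.exp(z - logsumexp(z))
        rho = np.zeros((self.J, self.K, self.C))
        for j in range(self.J):
            for k in range(self.K):
                act = self.active[j * self.K + k]
                if len(act) == 1:
                    rho[j, k, act[0]] = 1.0
                else:
                    z = np.concatenate([[0.0], theta[pos:pos + len(act) - 1]])
                    pos += len(act) - 1
                    rho[j, k, act] = np.exp(z - logsumexp(z))
        return pi, rho

    def score_matrix(self, patterns, theta):
        """R x n_free analytic per-pattern score (unweighted)."""
        pi, rho = self.unpack(theta)
        _, tau = _e_step(patterns, np.ones(len(patterns)), pi, rho)
        R = len(patterns)
        S = np.zeros((R, self.n_free))
        pos = 0
        if self.K > 1:
            S[:, pos:pos + self.K - 1] = tau[:, 1:] - pi[None, 1:]
            pos += self.K - 1
        for j in range(self.J):
            y = patterns[:, j]
            obs = y != MISSING_CODE
            for k in range(self.K):
                act = self.active[j * self.K + k]
                if len(act) <= 1:
                    continue
                for c in act[1:]:
                    g = np.zeros(R)
                    g[obs] = tau[obs, k] * ((y[obs] == c) - rho[j, k, c])
                    S[:, pos] = g
                    pos += 1
        return S

    def total_gradient(self, patterns, weights, theta):
        return weights @ self.score_matrix(patterns, theta)

    def hessian(self, patterns, weights, theta, h=1e-5):
        """Observed-information Hessian by central differences of the
        analytic gradient."""
        p = self.n_free
        H = np.zeros((p, p))
        for d in range(p):
            tp, tm = theta.copy(), theta.copy()
            tp[d] += h
            tm[d] -= h
            H[:, d] = (self.total_gradient(patterns, weights, tp)
                       - self.total_gradient(patterns, weights, tm)) / (2 * h)
        return (H + H.T) / 2.0


def _delta_method_ses(param, cov_theta, pi, rho):
    """Map Var(theta) back to SEs on the probability scale."""
    K, J, C = param.K, param.J, param.C
    se_pi = np.zeros(K)
    se_rho = np.zeros((J, K, C))
    boundary = np.zeros((J, K, C), dtype=bool)
    idx = {name: i for i, name in enumerate(param.names)}
    if K > 1:
        cols = [idx[("pi", k)] for k in range(1, K)]
        V = cov_theta[np.ix_(cols, cols)]
        Jac = np.zeros((K, K - 1))
        for k in range(K):
            for m in range(1, K):
                Jac[k, m - 1] = pi[k] * ((k == m) - pi[m])
        var = np.clip(np.diag(Jac @ V @ Jac.T), 0, None)
        se_pi = np.sqrt(var)
    for j in range(J):
        for k in range(K):
            act = param.active[j * K + k]
            for c in range(C):
                near0 = rho[j, k, c] <= BOUNDARY_EPS
                near1 = rho[j, k, c] >= 1 - BOUNDARY_EPS
                boundary[j, k, c] = near0 or near1
            if len(act) <= 1:
                continue
            cols = [idx[("rho", j, k, c)] for c in act[1:]]
            V = cov_theta[np.ix_(cols, cols)]
            Jac = np.zeros((len(act), len(act) - 1))
            for a, c in enumerate(act):
                for b, d in enumerate(act[1:]):
                    Jac[a, b] = rho[j, k, c] * ((c == d) - rho[j, k, d])
            var = np.clip(np.diag(Jac @ V @ Jac.T), 0, None)
            for a, c in enumerate(act):
                if not boundary[j, k, c]:
                    se_rho[j, k, c] = np.sqrt(var[a])
    return se_pi, se_rho, boundary


# ---------------------------------------------------------------------------
# fit statistics
# ---------------------------------------------------------------------------

def compute_bic(loglik: float, n_params: int, n: int) -> float:
    """BIC = -2*loglik + n_params * ln(n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return -2.0 * loglik + n_params * np.log(n)


def n_free_parameters(K: int, n_categories_per_item) -> int:
    """(K - 1) + K * sum_j (C_j - 1) free parameters of the mixture."""
    return (K - 1) + K * int(sum(c - 1 for c in n_categories_per_item))


def relative_entropy(tau: np.ndarray) -> float:
    """Separation index E = 1 - mean posterior entropy / ln K, in [0, 1].

    E = 1 when every posterior row is degenerate (perfect assignment),
    E = 0 when every row is uniform; by convention E = 1 for K = 1.
    """
    tau = np.asarray(tau, dtype=float)
    if tau.ndim != 2:
        raise ValueError("tau must be N x K")
    n, K = tau.shape
    if np.any(np.abs(tau.sum(axis=1) - 1.0) > 1e-8):
        raise ValueError("posterior rows must sum to 1 (within 1e-8)")
    if K == 1:
        return 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(tau > 0, tau * np.log(tau), 0.0)
    ent = -plogp.sum()
    return float(1.0 - ent / (n * np.log(K)))


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

@dataclass
class LCASpec:
    """Settings for one latent-class fit."""

    n_classes: int
    indicator_ids: list[str] | None = None
    n_starts: int = 50
    max_iter: int = 5000
    tol: float = 1e-8
    seed: int | None = None
    se_method: str | None = "observed_information"

    def __post_init__(self):
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


class LatentClassModel:
    """Finite mixture of independent multinomials over survey indicators.

    Parameters
    ----------
    responses : (N, J) int array
        Category codes per item; ``-1`` marks item nonresponse.
    n_classes : int
        Number of latent classes K.
    n_categories : int or sequence, optional
        Categories per item (default: 1 + max observed code, min 2).
    indicator_ids : list of str, optional
        Labels for the J items, used in summaries.
    groups : array-like, optional
        Cluster labels (households) for the sandwich SEs.
    """

    def __init__(self, responses, n_classes, n_categories=None,
                 indicator_ids=None, groups=None):
        responses = np.asarray(responses, dtype=np.int8)
        if responses.ndim != 2:
            raise ValueError("responses must be an N x J matrix")
        self.responses = responses
        self.n_classes = int(n_classes)
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        n, J = responses.shape
        if n <= self.n_classes:
            raise ValueError("need N > K observations")
        if n_categories is None:
            n_categories = max(2, int(responses.max()) + 1)
        self.n_categories = int(n_categories)
        for j in range(J):
            col = responses[:, j]
            if not (col != MISSING_CODE).any():
                raise ValueError(f"indicator {j} has no observed responses")
        self.indicator_ids = (list(indicator_ids) if indicator_ids is not None
                              else [f"item_{j}" for j in range(J)])
        self.groups = None if groups is None else np.asarray(groups, dtype=object)
        self._patterns, self._weights, self._inverse = _collapse(responses)

    @classmethod
    def from_dataset(cls, dataset: SurveyDataset, n_classes,
                     indicator_ids=None) -> "LatentClassModel":
        if indicator_ids is not None:
            dataset = dataset.select_indicators(list(indicator_ids))
        n_cats = max(ind.n_categories for ind in dataset.codebook.indicators)
        return cls(dataset.responses, n_classes, n_categories=n_cats,
                   indicator_ids=dataset.codebook.indicator_ids,
                   groups=dataset.household_id)

    # -- fitting -----------------------------------------------------------

    def fit(self, n_starts=50, max_iter=5000, tol=1e-8, seed=None,
            se_method="observed_information", strict_identifiability=False
            ) -> "LCAResults":
        """Run EM from ``n_starts`` random initializations, keep the best.

        Initial rho rows are Dirichlet(1) draws and the initial prevalence
        vector is uniform on the simplex.  The log-likelihood is
        non-decreasing within each run; classes are relabeled by descending
        prevalence afterwards.
        """
        K, C = self.n_classes, self.n_categories
        n, J = self.responses.shape
        n_patterns = len(self._patterns)
        if K > n_patterns:
            msg = (f"K={K} exceeds the {n_patterns} distinct response "
                   "patterns; the model is not identifiable")
            if strict_identifiability:
                raise IdentifiabilityError(msg)
            warnings.warn(msg, stacklevel=2)
        rng = np.random.default_rng(seed)
        best = None
        start_logliks = []
        any_converged = False
        for _ in range(max(1, n_starts)):
            pi0 = rng.dirichlet(np.ones(K))
            rho0 = rng.dirichlet(np.ones(C), size=(J, K))
            pi, rho, tau, ll, conv, hist = _em_single(
                self._patterns, self._weights, C, K, pi0, rho0, tol, max_iter)
            start_logliks.append(ll)
            any_converged = any_converged or conv
            if best is None or ll > best[3]:
                best = (pi, rho, tau, ll, conv, hist)
        if not any_converged:
            raise ConvergenceError(
                f"no EM restart converged in {max_iter} iterations",
                start_logliks=start_logliks)
        pi, rho, tau_p, ll, conv, hist = best
        pi, rho, tau_p = _sort_classes(pi, rho, tau_p)
        tau = tau_p[self._inverse]
        p = n_free_parameters(K, [C] * J)
        res = LCAResults(
            model=self,
            class_weights=pi,
            item_probs=rho,
            posteriors=tau,
            llf=ll,
            n_params=p,
            bic=compute_bic(ll, p, n),
            rel_entropy=relative_entropy(tau),
            converged=conv,
            start_logliks=np.array(start_logliks),
            em_history=np.array(hist),
            spec=LCASpec(K, self.indicator_ids, n_starts, max_iter, tol,
                         seed, se_method),
        )
        if se_method is not None:
            res.estimate_ses(method=se_method)
        return res


@dataclass
class LCAResults:
    """Fitted latent class model: parameters, posteriors, fit statistics."""

    model: LatentClassModel | None
    class_weights: np.ndarray        # pi, length K, descending
    item_probs: np.ndarray           # rho, J x K x C
    posteriors: np.ndarray           # tau, N x K
    llf: float
    n_params: int
    bic: float
    rel_entropy: float
    converged: bool
    start_logliks: np.ndarray
    em_history: np.ndarray = field(default_factory=lambda: np.array([]))
    spec: LCASpec | None = None
    se_class_weights: np.ndarray | None = None
    se_item_probs: np.ndarray | None = None
    boundary: np.ndarray | None = None
    se_method: str | None = None

    @property
    def n_classes(self) -> int:
        return len(self.class_weights)

    @property
    def n_obs(self) -> int:
        return self.posteriors.shape[0]

    @property
    def indicator_ids(self) -> list[str]:
        if self.spec is not None and self.spec.indicator_ids:
            return list(self.spec.indicator_ids)
        return [f"item_{j}" for j in range(self.item_probs.shape[0])]

    # -- prediction --------------------------------------------------------

    def predict_posterior(self, responses) -> np.ndarray:
        """Posterior class probabilities for new response vectors.

        ``tau_k`` is proportional to ``pi_k * prod_{j observed} rho[j,k,y_j]``;
        an all-missing vector returns the prevalence vector itself.
        """
        resp = np.asarray(responses, dtype=np.int8)
        single = resp.ndim == 1
        resp = np.atleast_2d(resp)
        J, _, C = self.item_probs.shape
        if resp.shape[1] != J:
            raise ValueError(f"expected {J} items, got {resp.shape[1]}")
        valid = (resp == MISSING_CODE) | ((resp >= 0) & (resp < C))
        if not valid.all():
            i, j = np.argwhere(~valid)[0]
            raise ValueError(
                f"response code {resp[i, j]} outside the codebook at "
                f"row {i}, item {j}")
        _, tau = _e_step(resp, np.ones(len(resp)),
                         self.class_weights, self.item_probs)
        return tau[0] if single else tau

    # -- standard errors ---------------------------------------------------

    def estimate_ses(self, method="observed_information", groups=None):
        """Attach SEs for pi and rho.

        ``observed_information`` inverts the Hessian of the observed-data
        log-likelihood in multinomial-logit coordinates and delta-methods
        back to probabilities.  ``sandwich`` wraps that bread around a
        cluster-aggregated score outer product (clusters = ``groups`` or the
        model's household ids) with a G/(G-1) small-sample factor.
        Boundary cells (rho in {0,1}) report SE 0 and a boundary flag.
        """
        if self.model is None:
            raise ValueError("results were loaded without a model; "
                             "SEs need the data")
        if not self.converged:
            raise ConvergenceError("cannot compute SEs for a non-converged fit")
        param = _Parameterization(self.class_weights, self.item_probs)
        patterns, weights = self.model._patterns, self.model._weights
        theta = param.pack(self.class_weights, self.item_probs)
        if param.n_free == 0:
            self.se_class_weights = np.zeros_like(self.class_weights)
            self.se_item_probs = np.zeros_like(self.item_probs)
            self.boundary = np.ones(self.item_probs.shape, dtype=bool)
            self.se_method = method
            return self
        H = param.hessian(patterns, weights, theta)
        info = -H
        eigvals = np.linalg.eigvalsh(info)
        if eigvals.min() <= 1e-10 * max(1.0, eigvals.max()):
            worst = param.names[int(np.argmin(np.abs(np.diag(info))))]
            raise SingularInformationError(
                f"observed information is singular near parameter {worst}")
        bread = np.linalg.inv(info)
        if method == "observed_information":
            cov = bread
        elif method == "sandwich":
            g = groups if groups is not None else self.model.groups
            if g is None:
                raise ValueError("sandwich SEs need cluster labels")
            g = np.asarray(g, dtype=object)
            S_pat = param.score_matrix(patterns, theta)
            S = S_pat[self.model._inverse]
            codes, inv = np.unique(g, return_inverse=True)
            G = len(codes)
            Sg = np.zeros((G, param.n_free))
            np.add.at(Sg, inv, S)
            meat = (G / (G - 1)) * (Sg.T @ Sg) if G > 1 else Sg.T @ Sg
            cov = bread @ meat @ bread
        else:
            raise ValueError(f"unknown SE method {method!r}")
        se_pi, se_rho, boundary = _delta_method_ses(
            param, cov, self.class_weights, self.item_probs)
        self.se_class_weights = se_pi
        self.se_item_probs = se_rho
        self.boundary = boundary
        self.se_method = method
        return self

    # -- goodness of fit ---------------------------------------------------

    def pearson_gof(self, n_bootstrap=200, seed=None, bootstrap_starts=5,
                    return_samples=False):
        """Pearson X2 over complete-case response patterns with a
        parametric-bootstrap p-value.

        Cells are the distinct fully-observed response patterns plus one
        aggregate cell carrying the expected mass of unobserved patterns
        (observed count 0).  With 3^J possible patterns the asymptotic
        chi-square reference is meaningless at survey scale, so the null
        distribution is simulated from the fitted model (refitting each
        replicate).
        """
        if self.model is None:
            raise ValueError("goodness of fit needs the fitted model's data")
        responses = self.model.responses
        complete = responses[(responses != MISSING_CODE).all(axis=1)]
        if len(complete) == 0:
            raise ValueError("no complete-response individuals")
        x2 = _pearson_x2(complete, self.class_weights, self.item_probs)
        if n_bootstrap <= 0:
            return x2, np.nan
        rng = np.random.default_rng(seed)
        n_c = len(complete)
        K, C = self.n_classes, self.item_probs.shape[2]
        exceed = 0
        samples = []
        for _ in range(n_bootstrap):
            sim = _simulate_responses(self.class_weights, self.item_probs,
                                      n_c, rng)
            boot_model = LatentClassModel(sim, K, n_categories=C)
            boot = boot_model.fit(n_starts=bootstrap_starts,
                                  max_iter=self.spec.max_iter if self.spec else 5000,
                                  tol=self.spec.tol if self.spec else 1e-8,
                                  seed=int(rng.integers(2**31 - 1)),
                                  se_method=None)
            x2_b = _pearson_x2(sim, boot.class_weights, boot.item_probs)
            samples.append(x2_b)
            if x2_b >= x2:
                exceed += 1
        pval = (1 + exceed) / (n_bootstrap + 1)
        if return_samples:
            return x2, pval, np.array(samples)
        return x2, pval

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Latent class measurement model",
            "=" * 64,
            f"N = {self.n_obs}   classes = {self.n_classes}   "
            f"items = {self.item_probs.shape[0]}",
            f"logLik = {self.llf:.3f}   params = {self.n_params}   "
            f"BIC = {self.bic:.2f}",
            f"relative entropy = {self.rel_entropy:.3f}   "
            f"converged = {self.converged}",
            "",
            "Class weights (pi):",
        ]
        for k, p in enumerate(self.class_weights):
            se = ("" if self.se_class_weights is None
                  else f" ({self.se_class_weights[k]:.3f})")
            lines.append(f"  class {k + 1}: {p:.3f}{se}")
        lines.append("")
        lines.append("Item-response probabilities rho (rows: categories):")
        cats = ["agree", "disagree", "dont_know"]
        J, K, C = self.item_probs.shape
        for j, iid in enumerate(self.indicator_ids):
            lines.append(f"  {iid}")
            for c in range(C):
                label = cats[c] if C == 3 else f"cat{c}"
                cells = []
                for k in range(K):
                    v = self.item_probs[j, k, c]
                    if self.se_item_probs is not None:
                        cells.append(f"{v:.2f} ({self.se_item_probs[j, k, c]:.2f})")
                    else:
                        cells.append(f"{v:.2f}")
                lines.append(f"    {label:<10} " + "  ".join(cells))
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "class_weights": self.class_weights.tolist(),
            "item_probs": self.item_probs.tolist(),
            "llf": self.llf,
            "n_params": self.n_params,
            "bic": self.bic,
            "rel_entropy": self.rel_entropy,
            "converged": bool(self.converged),
            "n_obs": int(self.n_obs),
            "start_logliks": self.start_logliks.tolist(),
            "se_class_weights": (None if self.se_class_weights is None
                                 else self.se_class_weights.tolist()),
            "se_item_probs": (None if self.se_item_probs is None
                              else self.se_item_probs.tolist()),
            "boundary": (None if self.boundary is None
                         else self.boundary.astype(int).tolist()),
            "se_method": self.se_method,
            "spec": None if self.spec is None else {
                "n_classes": self.spec.n_classes,
                "indicator_ids": self.spec.indicator_ids,
                "n_starts": self.spec.n_starts,
                "max_iter": self.spec.max_iter,
                "tol": self.spec.tol,
                "seed": self.spec.seed,
                "se_method": self.spec.se_method,
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "LCAResults":
        with open(path) as fh:
            d = json.load(fh)
        spec = None
        if d.get("spec"):
            spec = LCASpec(**d["spec"])
        n_obs = d["n_obs"]
        pi = np.array(d["class_weights"])
        res = cls(
            model=None,
            class_weights=pi,
            item_probs=np.array(d["item_probs"]),
            posteriors=np.tile(pi, (n_obs, 1)),
            llf=d["llf"],
            n_params=d["n_params"],
            bic=d["bic"],
            rel_entropy=d["rel_entropy"],
            converged=d["converged"],
            start_logliks=np.array(d["start_logliks"]),
            spec=spec,
            se_class_weights=(None if d["se_class_weights"] is None
                              else np.array(d["se_class_weights"])),
            se_item_probs=(None if d["se_item_probs"] is None
                           else np.array(d["se_item_probs"])),
            boundary=(None if d["boundary"] is None
                      else np.array(d["boundary"], dtype=bool)),
            se_method=d.get("se_method"),
        )
        return res


def _pearson_x2(complete_responses, pi, rho):
    patterns, counts, _ = _collapse(complete_responses)
    logf = _pattern_logf(patterns, rho)
    probs = np.exp(logsumexp(logf + np.log(np.maximum(pi, RHO_FLOOR)), axis=1))
    if np.any(probs <= 0):
        raise RuntimeError("zero expected mass in an observed pattern cell "
                           "(numerical underflow)")
    n = counts.sum()
    expected = n * probs
    x2 = float(((counts - expected) ** 2 / expected).sum())
    # one aggregate cell for all unobserved patterns: O = 0, Exp = n(1-sum p)
    rest = max(0.0, n * (1.0 - probs.sum()))
    return x2 + rest


def _simulate_responses(pi, rho, n, rng):
    K = len(pi)
    J, _, C = rho.shape
    z = rng.choice(K, size=n, p=np.asarray(pi) / np.sum(pi))
    out = np.empty((n, J), dtype=np.int8)
    u = rng.random((n, J))
    for k in range(K):
        mask = z == k
        if not mask.any():
            continue
        cum = np.cumsum(rho[:, k, :], axis=1)      # J x C
        cum = cum / cum[:, -1:]
        out[mask] = (u[mask, :, None] > cum[None, :, :]).sum(axis=2)
    return out


# ---------------------------------------------------------------------------
# functional wrappers (pipeline surface)
# ---------------------------------------------------------------------------

def fit_lca(dataset: SurveyDataset, spec: LCASpec) -> LCAResults:
    """Fit the latent class measurement model described by ``spec``."""
    model = LatentClassModel.from_dataset(dataset, spec.n_classes,
                                          indicator_ids=spec.indicator_ids)
    return model.fit(n_starts=spec.n_starts, max_iter=spec.max_iter,
                     tol=spec.tol, seed=spec.seed, se_method=spec.se_method)


def posterior(fit: LCAResults, responses) -> np.ndarray:
    return fit.predict_posterior(responses)


def pearson_gof(fit: LCAResults, n_bootstrap=200, seed=None, **kw):
    return fit.pearson_gof(n_bootstrap=n_bootstrap, seed=seed, **kw)


def estimate_ses(fit: LCAResults, method="observed_information", groups=None):
    fit.estimate_ses(method=method, groups=groups)
    return fit.se_item_probs, fit.se_class_weights
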
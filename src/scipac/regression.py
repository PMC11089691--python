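"""Penalized bulk-expression → phenotype regression (pipeline step 2).

The bulk model is an elastic net

    min_{b0, beta}  -(1/n) l(b0, beta)
                    + lam * { (1-a)/2 ||beta||_2^2 + a ||beta||_1 }

where ``l`` is the log-likelihood of

* logistic regression (binary phenotype),
* ordinary linear regression (continuous),
* Cox proportional hazards, Breslow tie handling (survival; no intercept),
* a right-tail proportional-odds model (ordinal):
  ``logit Pr(Y >= j+1 | x) = b0_j + beta' x``, so a positive coefficient
  means a higher chance of a *higher* level — keeping the sign convention
  of the association strength identical across phenotype kinds.

The mixing weight ``a`` defaults to 0.4; ``lam`` is chosen by k-fold
cross-validation (default 10 folds) minimizing the held-out deviance.

All four likelihoods are solved by one monotone FISTA (accelerated
proximal gradient) routine with backtracking: the ridge term is folded
into the smooth part, the l1 term is handled by soft-thresholding of the
gene coefficients (intercepts are never penalized).  Genes are
standardized (mean 0, sd 1 across bulk samples) inside the solver so the
penalty treats them comparably; coefficients are mapped back to the
normalized-expression scale before they are returned, which is the scale
the association strength needs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import ExpressionMatrix, Phenotype

__all__ = [
    "RegressionFit",
    "fit_elastic_net",
    "linear_predictor",
    "ordinal_penalized_negloglik",
]


# ---------------------------------------------------------------------------
# smooth losses: value and gradient of -(1/n) log-likelihood
# ---------------------------------------------------------------------------


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _log1pexp(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    big = x > 30
    out[big] = x[big]
    out[~big] = np.log1p(np.exp(x[~big]))
    return out


class _GaussianLoss:
    """-(1/n) Gaussian log-likelihood up to constants: (1/2n)||y - b0 - X beta||^2."""

    n_intercepts = 1

    def __init__(self, X: np.ndarray, y: np.ndarray):
        self.X, self.y, self.n = X, y, len(y)

    def init_intercepts(self) -> np.ndarray:
        return np.array([self.y.mean()])

    def value(self, b0: np.ndarray, eta: np.ndarray) -> float:
        r = self.y - b0[0] - eta
        return 0.5 * float(r @ r) / self.n

    def grad(self, b0, eta):
        r = self.y - b0[0] - eta
        return np.array([-r.sum() / self.n]), -r / self.n

    def held_out_deviance(self, b0, beta, X, y) -> np.ndarray:
        r = y - (b0[0] if len(b0) else 0.0) - X @ beta
        return r**2


class _LogisticLoss:
    n_intercepts = 1

    def __init__(self, X: np.ndarray, y: np.ndarray):
        self.X, self.y, self.n = X, y, len(y)

    def init_intercepts(self) -> np.ndarray:
        p = np.clip(self.y.mean(), 1e-6, 1 - 1e-6)
        return np.array([np.log(p / (1 - p))])

    def value(self, b0, eta):
        z = b0[0] + eta
        return float(np.sum(_log1pexp(z) - self.y * z)) / self.n

    def grad(self, b0, eta):
        r = _sigmoid(b0[0] + eta) - self.y
        return np.array([r.sum() / self.n]), r / self.n

    def held_out_deviance(self, b0, beta, X, y) -> np.ndarray:
        z = b0[0] + X @ beta
        return 2.0 * (_log1pexp(z) - y * z)


class _OrdinalLoss:
    """Right-tail proportional odds: Pr(Y >= j+1 | x) = sigmoid(b0_j + eta).

    Intercepts b0_1 > b0_2 > ... > b0_{J-1} (strictly) so the right-tail
    probabilities decrease in j and every category probability is positive.
    The negative log-likelihood is convex in (b0, beta); parameter points
    violating the ordering are given value +inf, which the backtracking
    line search treats as an automatic step rejection.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, n_levels: int):
        self.X, self.n = X, len(y)
        self.J = int(n_levels)
        self.y = np.asarray(y, dtype=int)
        if self.y.min() < 1 or self.y.max() > self.J:
            raise ValueError("ordinal levels out of range")
        self.n_intercepts = self.J - 1

    def init_intercepts(self) -> np.ndarray:
        # logits of empirical right-tail probabilities, strictly ordered
        J = self.J
        tail = np.array([(self.y >= j + 1).mean() for j in range(1, J)])
        tail = np.clip(tail, 1e-4, 1 - 1e-4)
        b0 = np.log(tail / (1 - tail))
        # enforce strict decrease if ties in the empirical tails
        for j in range(1, len(b0)):
            if b0[j] >= b0[j - 1]:
                b0[j] = b0[j - 1] - 1e-6
        return b0

    def _category_probs(self, b0, eta):
        """n x J matrix of category probabilities; None if ordering invalid."""
        if np.any(np.diff(b0) >= 0):
            return None
        right = np.ones((self.n, self.J + 1))
        right[:, self.J] = 0.0
        for j in range(1, self.J):
            right[:, j] = _sigmoid(b0[j - 1] + eta)
        P = right[:, :-1] - right[:, 1:]
        if np.any(P <= 0):
            return None
        return P

    def value(self, b0, eta):
        P = self._category_probs(b0, eta)
        if P is None:
            return np.inf
        return -float(np.sum(np.log(P[np.arange(self.n), self.y - 1]))) / self.n

    def grad(self, b0, eta):
        y = self.y
        J = self.J
        # r_j = Pr(Y >= j+1), j = 1..J-1
        r = np.empty((self.n, J + 1))
        r[:, 0] = 1.0
        r[:, J] = 0.0
        for j in range(1, J):
            r[:, j] = _sigmoid(b0[j - 1] + eta)
        P = r[np.arange(self.n), y - 1] - r[np.arange(self.n), y]
        P = np.maximum(P, 1e-300)
        gb0 = np.zeros(J - 1)
        geta = np.zeros(self.n)
        for j in range(1, J):  # intercept index j -> r[:, j]
            d = r[:, j] * (1.0 - r[:, j])
            upper = y == j  # P(y) = r_{j-1} - r_j, term -dr_j
            lower = y == j + 1  # P(y) = r_j - r_{j+1}, term +dr_j
            contrib = np.where(upper, -d, 0.0) + np.where(lower, d, 0.0)
            contrib /= P
            gb0[j - 1] = -contrib.sum() / self.n
            geta -= contrib / self.n
        return gb0, geta

    def held_out_deviance(self, b0, beta, X, y) -> np.ndarray:
        eta = X @ beta
        n = len(y)
        y = np.asarray(y, dtype=int)
        right = np.ones((n, self.J + 1))
        right[:, self.J] = 0.0
        for j in range(1, self.J):
            right[:, j] = _sigmoid(b0[j - 1] + eta)
        P = right[np.arange(n), y - 1] - right[np.arange(n), y]
        return -2.0 * np.log(np.maximum(P, 1e-300))


class _CoxLoss:
    """Breslow partial likelihood; no intercept.

    ``value`` and ``grad`` take eta in the caller's (original) observation
    order; sorting by decreasing time happens internally."""

    n_intercepts = 0

    def __init__(self, X: np.ndarray, time: np.ndarray, event: np.ndarray):
        self.order = np.argsort(-time, kind="stable")  # decreasing time
        self.time = time[self.order]
        self.event = event[self.order].astype(bool)
        self.n = len(time)

    def init_intercepts(self) -> np.ndarray:
        return np.zeros(0)

    def _risk_denominators(self, eta):
        """For each index i (sorted by decreasing time), log-sum-exp of eta
        over the risk set {j: t_j >= t_i}.  Ties: all subjects with the same
        time belong to every risk set at that time (Breslow), so each tied
        block uses its last index in the decreasing-time ordering."""
        shift = eta.max()
        csum = np.cumsum(np.exp(eta - shift))
        last_idx = self._tie_last_index()
        return shift + np.log(csum[last_idx]), csum, shift, last_idx

    def _tie_last_index(self):
        t = self.time
        last = np.arange(self.n)
        for i in range(self.n - 2, -1, -1):
            if t[i] == t[i + 1]:
                last[i] = last[i + 1]
        return last

    def value(self, b0, eta_unsorted):
        eta = eta_unsorted[self.order]
        logdenom, _, _, _ = self._risk_denominators(eta)
        ll = np.sum(eta[self.event] - logdenom[self.event])
        return -float(ll) / self.n

    def grad(self, b0, eta_unsorted):
        eta = eta_unsorted[self.order]
        shift = eta.max()
        w = np.exp(eta - shift)
        csum = np.cumsum(w)
        last_idx = self._tie_last_index()
        denom = csum[last_idx]
        # risk set of event e = indices 0..last_idx[e] (decreasing-time order),
        # so subject i contributes to every event e with last_idx[e] >= i:
        # coverage_i = sum_{e: last_idx[e] >= i} 1/denom_e
        inv_denom = np.where(self.event, 1.0 / denom, 0.0)
        s = np.zeros(self.n + 1)
        np.add.at(s, last_idx[self.event] + 1, inv_denom[self.event])
        cum = np.cumsum(s)
        coverage = cum[-1] - cum[:-1]
        g_sorted = -(self.event.astype(float) - w * coverage) / self.n
        g = np.empty(self.n)
        g[self.order] = g_sorted
        return np.zeros(0), g

    def held_out_deviance(self, b0, beta, X, y) -> np.ndarray:
        raise NotImplementedError  # survival CV uses the V&VH construction


def _cox_partial_loglik(eta: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow partial log-likelihood (not scaled by n)."""
    order = np.argsort(-time, kind="stable")
    eta, time, event = eta[order], time[order], event[order].astype(bool)
    shift = eta.max()
    csum = np.cumsum(np.exp(eta - shift))
    last = np.arange(len(time))
    for i in range(len(time) - 2, -1, -1):
        if time[i] == time[i + 1]:
            last[i] = last[i + 1]
    logdenom = shift + np.log(csum[last])
    return float(np.sum(eta[event] - logdenom[event]))


# ---------------------------------------------------------------------------
# monotone FISTA with backtracking
# ---------------------------------------------------------------------------


def _fista(
    loss,
    X: np.ndarray,
    lam: float,
    alpha_mix: float,
    b0_init: np.ndarray,
    beta_init: np.ndarray,
    tol: float = 1e-7,
    max_iter: int = 10000,
    trace: list | None = None,
):
    """Minimize loss + lam*(1-a)/2||beta||^2 + lam*a||beta||_1.

    Monotone variant: the accepted iterate never increases the objective,
    with momentum restarts when the extrapolated point fails.
    """
    n_int = loss.n_intercepts
    ridge = lam * (1.0 - alpha_mix)
    l1 = lam * alpha_mix

    def smooth(b0, beta):
        return loss.value(b0, X @ beta) + 0.5 * ridge * float(beta @ beta)

    def smooth_grad(b0, beta):
        gb0, geta = loss.grad(b0, X @ beta)
        return gb0, X.T @ geta + ridge * beta

    def objective(b0, beta):
        return smooth(b0, beta) + l1 * float(np.abs(beta).sum())

    b0, beta = b0_init.copy(), beta_init.copy()
    yb0, ybeta = b0.copy(), beta.copy()
    t_mom = 1.0
    L = 1.0
    F = objective(b0, beta)
    if trace is not None:
        trace.append(F)
    for _ in range(max_iter):
        fy = smooth(yb0, ybeta)
        if not np.isfinite(fy):
            # extrapolated point infeasible (ordinal ordering): restart momentum
            yb0, ybeta = b0.copy(), beta.copy()
            t_mom = 1.0
            fy = smooth(yb0, ybeta)
        gb0, gbeta = smooth_grad(yb0, ybeta)
        # backtracking on L
        while True:
            nb0 = yb0 - gb0 / L
            nbeta = ybeta - gbeta / L
            nbeta = np.sign(nbeta) * np.maximum(np.abs(nbeta) - l1 / L, 0.0)
            fn = smooth(nb0, nbeta)
            if np.isfinite(fn):
                db0, dbeta = nb0 - yb0, nbeta - ybeta
                quad = fy + float(gb0 @ db0 + gbeta @ dbeta) + 0.5 * L * (
                    float(db0 @ db0) + float(dbeta @ dbeta)
                )
                if fn <= quad + 1e-12:
                    break
            L *= 2.0
            if L > 1e14:
                break
        Fn = fn + l1 * float(np.abs(nbeta).sum())
        if Fn > F:  # monotone safeguard: reject, restart momentum from best point
            yb0, ybeta = b0.copy(), beta.copy()
            t_mom = 1.0
            gb0, gbeta = smooth_grad(yb0, ybeta)
            nb0 = yb0 - gb0 / L
            nbeta = ybeta - gbeta / L
            nbeta = np.sign(nbeta) * np.maximum(np.abs(nbeta) - l1 / L, 0.0)
            Fn = objective(nb0, nbeta)
            if Fn > F:
                break  # no further progress possible at this L
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
        yb0 = nb0 + ((t_mom - 1.0) / t_new) * (nb0 - b0)
        ybeta = nbeta + ((t_mom - 1.0) / t_new) * (nbeta - beta)
        b0, beta, t_mom = nb0, nbeta, t_new
        if trace is not None:
            trace.append(Fn)
        if abs(F - Fn) <= tol * max(1.0, abs(F)):
            F = Fn
            break
        F = Fn
        L = max(L / 2.0, 1e-10)  # allow the step size to grow back
    return b0, beta


# ---------------------------------------------------------------------------
# public fit
# ---------------------------------------------------------------------------


@dataclass
class RegressionFit:
    """Fitted penalized bulk model.

    ``beta`` and ``intercepts`` are on the normalized-expression scale
    (the standardization applied inside the solver has been undone), so
    ``intercepts + beta @ g`` is directly comparable across bulk samples
    and cluster centroids.
    """

    kind: str
    intercepts: np.ndarray
    beta: np.ndarray
    alpha_mix: float
    lambda_penalty: float
    cv_folds: int
    gene_ids: list[str] = field(default_factory=list)
    n_levels: int | None = None
    cv_lambdas: np.ndarray | None = None
    cv_deviance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta must be finite")
        if self.kind == "survival" and self.intercepts.size:
            raise ValueError("Cox fit must have no intercept")
        if self.kind == "ordinal" and np.any(np.diff(self.intercepts) >= 0):
            raise ValueError("ordinal intercepts must be strictly decreasing")


def _make_loss(X: np.ndarray, pheno: Phenotype):
    if pheno.kind == "binary":
        return _LogisticLoss(X, pheno.values)
    if pheno.kind == "continuous":
        return _GaussianLoss(X, pheno.values)
    if pheno.kind == "ordinal":
        return _OrdinalLoss(X, pheno.values, pheno.n_levels)
    if pheno.kind == "survival":
        return _CoxLoss(X, pheno.time, pheno.event)
    raise ValueError(pheno.kind)


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe, mu, sd_safe


def _lambda_max(loss, X: np.ndarray, alpha_mix: float) -> float:
    b0 = loss.init_intercepts()
    # refine unpenalized intercepts by a few smooth-only steps
    beta0 = np.zeros(X.shape[1])
    if loss.n_intercepts:
        b0, _ = _fista(loss, X[:, :1] * 0.0, 0.0, alpha_mix, b0, np.zeros(1),
                       tol=1e-10, max_iter=500)
    _, geta = loss.grad(b0, X @ beta0)
    gmax = float(np.abs(X.T @ geta).max())
    a = max(alpha_mix, 1e-3)
    return max(gmax / a, 1e-10)


def _cv_folds_indices(pheno: Phenotype, n: int, k: int, rng: np.random.Generator):
    """Seeded fold assignment, stratified by class (binary/ordinal) or event
    status (survival)."""
    fold = np.empty(n, dtype=int)
    if pheno.kind in ("binary", "ordinal"):
        strata = pheno.values.astype(int)
    elif pheno.kind == "survival":
        strata = pheno.event
    else:
        strata = np.zeros(n, dtype=int)
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        idx = rng.permutation(idx)
        fold[idx] = np.arange(len(idx)) % k
    return fold


def fit_elastic_net(
    bulk: ExpressionMatrix,
    pheno: Phenotype,
    alpha_mix: float = 0.4,
    cv_folds: int = 10,
    seed: int = 0,
    lambda_penalty: float | None = None,
    n_lambdas: int = 30,
    lambda_min_ratio: float = 0.01,
    tol: float = 1e-7,
    max_iter: int = 10000,
) -> RegressionFit:
    """Fit the elastic net, choosing the penalty strength by cross-validation.

    If ``lambda_penalty`` is given, CV is skipped and the model is fitted at
    that penalty (used for bootstrap refits, which reuse the original
    CV-selected penalty).
    """
    if not (0.0 <= alpha_mix <= 1.0):
        raise ValueError("alpha_mix must lie in [0, 1]")
    if bulk.n_obs != len(pheno):
        raise ValueError("bulk samples and phenotype length differ")
    X_raw = bulk.values
    X, mu, sd = _standardize(X_raw)
    n, p = X.shape
    loss = _make_loss(X, pheno)
    lam_max = _lambda_max(loss, X, alpha_mix)
    cv_lams = cv_dev = None

    if lambda_penalty is None:
        lams = np.geomspace(lam_max * 1.001, lam_max * lambda_min_ratio, n_lambdas)
        rng = np.random.default_rng(seed)
        fold = _cv_folds_indices(pheno, n, cv_folds, rng)
        _check_folds(pheno, fold, cv_folds)
        dev = np.zeros((cv_folds, n_lambdas))
        for f in range(cv_folds):
            tr = fold != f
            te = ~tr
            dev[f] = _cv_path_deviance(
                X, pheno, tr, te, lams, alpha_mix, tol=max(tol, 1e-5),
                max_iter=max_iter,
            )
        mean_dev = dev.mean(axis=0)
        lambda_penalty = float(lams[int(np.argmin(mean_dev))])
        cv_lams, cv_dev = lams, mean_dev

    # final fit on the full data, warm-started along the path down to lambda
    b0 = loss.init_intercepts()
    beta = np.zeros(p)
    path = np.geomspace(lam_max * 1.001, lambda_penalty, 8)
    for lam in path:
        b0, beta = _fista(loss, X, lam, alpha_mix, b0, beta,
                          tol=tol, max_iter=max_iter)

    # map back to the normalized-expression scale
    beta_orig = beta / sd
    intercepts = b0.copy()
    if loss.n_intercepts:
        intercepts = b0 - float(beta_orig @ mu)
    return RegressionFit(
        kind=pheno.kind,
        intercepts=intercepts,
        beta=beta_orig,
        alpha_mix=alpha_mix,
        lambda_penalty=float(lambda_penalty),
        cv_folds=cv_folds,
        gene_ids=list(bulk.gene_ids),
        n_levels=pheno.n_levels,
        cv_lambdas=cv_lams,
        cv_deviance=cv_dev,
    )


def _check_folds(pheno: Phenotype, fold: np.ndarray, k: int) -> None:
    for f in range(k):
        tr = fold != f
        if pheno.kind == "binary" and len(np.unique(pheno.values[tr])) < 2:
            raise ValueError("CV fold with a single class; reduce cv_folds")
        if pheno.kind == "survival" and pheno.event[tr].sum() < 1:
            raise ValueError("CV fold with no events; reduce cv_folds")


def _subset_pheno(pheno: Phenotype, idx: np.ndarray) -> Phenotype:
    if pheno.kind == "survival":
        return Phenotype("survival", None, time=pheno.time[idx],
                         event=pheno.event[idx])
    return Phenotype(pheno.kind, pheno.values[idx],
                     n_levels=pheno.n_levels if pheno.kind == "ordinal" else None)


def _cv_path_deviance(X, pheno, tr, te, lams, alpha_mix, tol, max_iter):
    """Mean held-out deviance along the penalty path for one fold."""
    tr_idx = np.flatnonzero(tr)
    te_idx = np.flatnonzero(te)
    Xtr, Xte = X[tr_idx], X[te_idx]
    ptr = _subset_pheno(pheno, tr_idx)
    loss_tr = _make_loss(Xtr, ptr)
    b0 = loss_tr.init_intercepts()
    beta = np.zeros(X.shape[1])
    out = np.empty(len(lams))
    for i, lam in enumerate(lams):
        b0, beta = _fista(loss_tr, Xtr, lam, alpha_mix, b0, beta,
                          tol=tol, max_iter=max_iter)
        if pheno.kind == "survival":
            # Verweij & Van Houwelingen: dev = -2 (pl_full - pl_train)
            eta_all = X @ beta
            pl_full = _cox_partial_loglik(eta_all, pheno.time, pheno.event)
            pl_tr = _cox_partial_loglik(eta_all[tr_idx], pheno.time[tr_idx],
                                        pheno.event[tr_idx])
            out[i] = -2.0 * (pl_full - pl_tr)
        else:
            pte = _subset_pheno(pheno, te_idx)
            loss_te = _make_loss(Xte, pte)
            out[i] = float(np.mean(
                loss_te.held_out_deviance(b0, beta, Xte, pte.values)
            ))
    return out


def linear_predictor(fit: RegressionFit, X: ExpressionMatrix | np.ndarray) -> np.ndarray:
    """Per-observation score ``b0 + beta' x`` (Cox and ordinal: ``beta' x``
    only; ordinal intercepts are reported separately on the fit)."""
    if isinstance(X, ExpressionMatrix):
        if X.gene_ids != fit.gene_ids:
            raise ValueError("gene ids of X do not match the fit")
        vals = X.values
    else:
        vals = np.asarray(X, dtype=float)
        if vals.shape[1] != len(fit.beta):
            raise ValueError("gene dimension of X does not match the fit")
    eta = vals @ fit.beta
    if fit.kind in ("binary", "continuous"):
        eta = eta + fit.intercepts[0]
    return eta


def ordinal_penalized_negloglik(
    intercepts: np.ndarray,
    beta: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    alpha_mix: float,
    lambda_penalty: float,
    n_levels: int | None = None,
) -> float:
    """Penalized negative log-likelihood of the right-tail proportional-odds
    model: ``-(1/n) sum_i log Pr(Y_i = y_i) + lam*(a||beta||_1 + (1-a)/2||beta||_2^2)``.

    The penalty applies to ``beta`` only, never to the intercepts.
    """
    intercepts = np.asarray(intercepts, dtype=float)
    beta = np.asarray(beta, dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.any(np.diff(intercepts) >= 0):
        raise ValueError("intercept ordering violated")
    J = n_levels if n_levels is not None else len(intercepts) + 1
    loss = _OrdinalLoss(X, y, J)
    val = loss.value(intercepts, X @ beta)
    if not np.isfinite(val):
        raise ValueError("intercept ordering violated")
    penalty = lambda_penalty * (
        alpha_mix * float(np.abs(beta).sum())
        + 0.5 * (1.0 - alpha_mix) * float(beta @ beta)
    )
    return float(val + penalty)
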
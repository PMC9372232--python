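"""L1-regularized Cox proportional hazards fitting.

Implements the glmnet-style algorithm: iteratively reweighted least squares
on the weighted Breslow partial likelihood, with each quadratic subproblem
solved by cyclic coordinate descent and soft thresholding. Predictors are
standardized internally; a penalty mask exempts covariates (here, ancestry
principal components) from the L1 penalty so they are never shrunk to zero.

The objective minimized at each ``lam`` on the path is::

    -(1/n) * pll(beta) + lam * sum_j pf_j * |beta_j|

with ``pll`` the weighted Breslow partial log-likelihood (sample weights
normalized to mean one) and ``pf_j`` the per-predictor penalty factor
(0 for unpenalized covariates, 1 otherwise), beta on the standardized scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from sklearn.base import BaseEstimator

from ._cox import (
    ConvergenceError,
    breslow_loglik,
    breslow_loglik_sorted,
    build_risk_index,
    cox_newton,
    lp_grad_hess,
)

__all__ = [
    "cox_partial_loglik",
    "fit_lasso_path",
    "cross_validate",
    "export_weights",
    "kkt_residuals",
    "LassoPath",
    "CVResult",
    "FittedModel",
    "LassoCoxPHS",
]


def cox_partial_loglik(betas, X, event_ages, event_flags, weights=None, ties="breslow"):
    """Weighted Cox partial log-likelihood at ``betas`` (Breslow ties).

    Unit weights reduce to the classical partial likelihood. Ages must be
    positive; at least one event is required.
    """
    if ties != "breslow":
        raise NotImplementedError(f"ties method {ties!r} not supported (breslow only)")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    betas = np.atleast_1d(np.asarray(betas, dtype=float))
    if X.shape[1] != betas.shape[0]:
        raise ValueError("betas and X have incompatible shapes")
    return breslow_loglik(X @ betas, event_ages, event_flags, weights)


@njit(cache=True)
def _cd_pass(X, r, hn, beta, hx2, lam_pf, active):  # pragma: no cover - numba
    n, p = X.shape
    maxd = 0.0
    for j in range(p):
        if not active[j]:
            continue
        hj = hx2[j]
        if hj <= 0.0:
            continue
        bj = beta[j]
        acc = bj * hj
        for i in range(n):
            acc += hn[i] * X[i, j] * r[i]
        lp = lam_pf[j]
        if acc > lp:
            bnew = (acc - lp) / hj
        elif acc < -lp:
            bnew = (acc + lp) / hj
        else:
            bnew = 0.0
        d = bnew - bj
        if d != 0.0:
            for i in range(n):
                r[i] -= X[i, j] * d
            beta[j] = bnew
            ad = abs(d)
            if ad > maxd:
                maxd = ad
    return maxd


def _active_refine(X, z, hn, beta, lam_pf, active):
    """Exact Newton solve of the quadratic subproblem on the active set.

    With the active signs fixed, the L1 term is linear, so the restricted
    minimizer solves ``G beta_A = b_A - lam*pf*sign``. Penalized coordinates
    whose solution flips sign are projected to zero (they leave the active
    set). Used when plain cyclic descent crawls on strongly correlated
    active predictors.
    """
    A = np.flatnonzero(active)
    if A.size == 0:
        return
    XA = X[:, A]
    Xw = XA * hn[:, None]
    G = Xw.T @ XA
    b = Xw.T @ z
    s = np.sign(beta[A])
    rhs = b - lam_pf[A] * s
    try:
        sol = np.linalg.solve(G, rhs)
    except np.linalg.LinAlgError:
        sol, *_ = np.linalg.lstsq(G, rhs, rcond=None)
    if not np.all(np.isfinite(sol)):
        return
    # step toward the restricted minimizer, stopping at the first sign
    # crossing of a penalized coordinate (the subgradient changes there)
    direction = sol - beta[A]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_cross = -beta[A] / direction
    penal = (lam_pf[A] > 0) & (s != 0) & (np.sign(sol) != s)
    t_candidates = t_cross[penal & (t_cross > 0)]
    t = min(1.0, t_candidates.min()) if t_candidates.size else 1.0
    newA = beta[A] + t * direction
    crossed = penal & (np.abs(t_cross - t) < 1e-15)
    newA[crossed] = 0.0
    beta[A] = newA


def _cd_solve(X, r, hn, beta, hx2, lam_pf, tol, max_outer=200):
    """Coordinate descent to convergence with an active-set strategy.

    Iterates over the current active set (nonzero or unpenalized) until the
    coefficient changes fall below ``tol``, then runs one full pass; the
    solve is complete when the full pass neither moves a coefficient nor
    admits a new active one. If the active sweeps stall (ill-conditioned
    active set), the restricted quadratic is solved exactly by
    :func:`_active_refine`. The residual is refreshed from the stored
    working response to stop float drift from the incremental updates.
    """
    p = X.shape[1]
    all_active = np.ones(p, dtype=np.bool_)
    z = r + X @ beta  # working response, fixed within this quadratic solve
    for _ in range(max_outer):
        active = (beta != 0.0) | (lam_pf == 0.0)
        for _ in range(200):
            d = _cd_pass(X, r, hn, beta, hx2, lam_pf, active)
            if d < tol:
                break
        else:
            _active_refine(X, z, hn, beta, lam_pf, active)
            r[:] = z - X @ beta
            for _ in range(50):
                d = _cd_pass(X, r, hn, beta, hx2, lam_pf, active)
                if d < tol:
                    break
        if not np.all(np.isfinite(beta)):
            raise ConvergenceError("non-finite coefficients in coordinate descent")
        r[:] = z - X @ beta
        d_full = _cd_pass(X, r, hn, beta, hx2, lam_pf, all_active)
        if d_full < tol:
            return
    raise ConvergenceError("coordinate descent failed to converge")


@dataclass
class LassoPath:
    """Solution path of the penalized Cox model (coefficients on input scale)."""

    lambdas: np.ndarray              # decreasing
    coefs: np.ndarray                # (n_lambda, p)
    loglik: np.ndarray               # weighted pll at each solution
    penalty_mask: np.ndarray         # True where penalized
    feature_mean: np.ndarray
    feature_sd: np.ndarray

    @property
    def n_nonzero(self):
        return (self.coefs != 0).sum(axis=1)


def _standardize(X):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"constant predictor column(s) at indices {bad.tolist()}")
    return (X - mu) / sd, mu, sd


def _normalized_weights(weights, n):
    if weights is None:
        return np.ones(n)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or not np.all(np.isfinite(w)) or w.sum() <= 0:
        raise ValueError("weights must be finite, non-negative, not all zero")
    return w * (n / w.sum())


def _irls_fit(Xso, Xso2, idx, beta, lam, pf, n, tol, max_irls):
    """Solve the penalized problem at one lambda by IRLS + coordinate descent.

    ``Xso`` is the standardized design matrix in risk-index (ascending time)
    order; ``Xso2`` its elementwise square.
    """
    lam_pf = lam * pf
    for _ in range(max_irls):
        lp = Xso @ beta
        grad, hess = lp_grad_hess(idx, lp)
        hess = np.maximum(hess, 1e-9)
        hn = hess / n
        r = grad / hess  # residual of working response z = lp + g/h against lp
        beta_old = beta.copy()
        hx2 = hn @ Xso2
        _cd_solve(Xso, r, hn, beta, hx2, lam_pf, tol=0.1 * tol)
        if np.max(np.abs(beta - beta_old)) < tol:
            return beta
    raise ConvergenceError(f"IRLS did not converge at lambda={lam:.6g}")


def _lambda_max(Xso, Xso2, idx, pf, n, tol, max_irls):
    """Smallest lambda with all penalized coefficients zero, plus the
    corresponding warm-start solution (unpenalized coordinates fitted)."""
    beta0 = np.zeros(Xso.shape[1])
    if np.any(pf == 0):
        # fit the unpenalized block alone: huge lambda freezes penalized coords
        beta0 = _irls_fit(Xso, Xso2, idx, beta0, 1e30, pf, n, tol, max_irls)
    lp = Xso @ beta0
    grad, _ = lp_grad_hess(idx, lp)
    g = (grad @ Xso) / n
    pen = pf > 0
    if not pen.any():
        raise ValueError("no penalized predictors: nothing to select")
    # nudged above the convergence error of the unpenalized pre-fit so the
    # argmax coordinate sits strictly inside the soft threshold and the
    # first path point is exactly sparse
    lmax = float(np.max(np.abs(g[pen]) / pf[pen])) * (1.0 + 1e-6)
    return lmax, beta0


def fit_lasso_path(
    X,
    event_ages,
    event_flags,
    weights=None,
    penalty_mask=None,
    n_lambda=100,
    lambda_min_ratio=1e-4,
    lambdas=None,
    tol=1e-8,
    max_irls=100,
) -> LassoPath:
    """Fit the L1-penalized Cox coefficient path.

    Parameters
    ----------
    penalty_mask : bool array (p,), optional
        True for predictors subject to the L1 penalty (SNP allele counts),
        False for unpenalized covariates (principal components). Default: all
        penalized.
    lambdas : array, optional
        Explicit penalty grid (decreasing). When omitted, a log-spaced grid of
        ``n_lambda`` values from ``lambda_max`` down to
        ``lambda_max * lambda_min_ratio`` is used.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if penalty_mask is None:
        penalty_mask = np.ones(p, dtype=bool)
    else:
        penalty_mask = np.asarray(penalty_mask, dtype=bool)
        if penalty_mask.shape != (p,):
            raise ValueError("penalty_mask shape mismatch")
    pf = penalty_mask.astype(float)

    w = _normalized_weights(weights, n)
    idx = build_risk_index(event_ages, event_flags, w)
    Xs, mu, sd = _standardize(X)
    Xso = np.asfortranarray(Xs[idx.order])  # column access dominates in CD
    Xso2 = Xso**2

    lmax, beta = _lambda_max(Xso, Xso2, idx, pf, n, tol, max_irls)
    if lambdas is None:
        lambdas = np.exp(
            np.linspace(np.log(lmax), np.log(lmax * lambda_min_ratio), n_lambda)
        )
        lambdas[0] = lmax  # exact, not through exp/log round trip
    else:
        lambdas = np.asarray(lambdas, dtype=float)
        if np.any(np.diff(lambdas) > 0):
            raise ValueError("lambda grid must be decreasing")

    coefs = np.empty((len(lambdas), p))
    lls = np.empty(len(lambdas))
    for k, lam in enumerate(lambdas):
        beta = _irls_fit(Xso, Xso2, idx, beta, lam, pf, n, tol, max_irls)
        coefs[k] = beta / sd
        lls[k] = breslow_loglik_sorted(idx, Xso @ beta)
    return LassoPath(
        lambdas=lambdas,
        coefs=coefs,
        loglik=lls,
        penalty_mask=penalty_mask,
        feature_mean=mu,
        feature_sd=sd,
    )


def kkt_residuals(path: LassoPath, X, event_ages, event_flags, weights=None):
    """Per-lambda KKT violations of the penalized stationarity conditions.

    For each path point, returns ``max_j v_j`` where for penalized zero
    coefficients ``v_j = max(0, |g_j| - lam)`` and for active or unpenalized
    coefficients ``v_j = |g_j - lam * pf_j * sign(beta_j)|``, with ``g`` the
    gradient of the mean partial log-likelihood on the standardized scale.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    w = _normalized_weights(weights, n)
    idx = build_risk_index(event_ages, event_flags, w)
    Xs = (X - path.feature_mean) / path.feature_sd
    pf = path.penalty_mask.astype(float)
    out = np.empty(len(path.lambdas))
    for k, lam in enumerate(path.lambdas):
        beta_std = path.coefs[k] * path.feature_sd
        lp = Xs[idx.order] @ beta_std
        grad, _ = lp_grad_hess(idx, lp)
        g = (grad @ Xs[idx.order]) / n
        v = np.where(
            (pf > 0) & (beta_std == 0),
            np.maximum(0.0, np.abs(g) - lam * pf),
            np.abs(g - lam * pf * np.sign(beta_std)),
        )
        out[k] = v.max()
    return out


@dataclass
class CVResult:
    lambdas: np.ndarray
    mean_deviance: np.ndarray
    se_deviance: np.ndarray
    lambda_min: float
    lambda_min_index: int
    fold_ids: np.ndarray


def _make_folds(rng, n, k, event_flags, max_retry=50):
    ev = np.asarray(event_flags, dtype=bool)
    # every training complement needs an event; each held-out fold should
    # carry one too whenever there are enough events to go around (with
    # k > #events, e.g. leave-one-out, censored-only folds are fine: their
    # deviance contribution is still defined)
    want_fold_events = ev.sum() >= k
    for _ in range(max_retry):
        perm = rng.permutation(n)
        fold_ids = np.empty(n, dtype=int)
        fold_ids[perm] = np.arange(n) % k
        ok = all(
            ev[fold_ids != f].sum() >= 1
            and (not want_fold_events or ev[fold_ids == f].sum() >= 1)
            for f in range(k)
        )
        if ok:
            return fold_ids
    raise ValueError(f"could not build {k} folds with >=1 event per fold")


def cross_validate(
    X,
    event_ages,
    event_flags,
    weights=None,
    penalty_mask=None,
    k=10,
    seed=0,
    n_lambda=100,
    lambda_min_ratio=1e-4,
    tol=1e-8,
    max_irls=100,
):
    """Select lambda by k-fold cross-validated partial-likelihood deviance.

    The deviance of fold ``f`` at each lambda follows the Verweij &
    van Houwelingen construction: ``-2 * (pll_all(beta_-f) -
    pll_train(beta_-f))``, i.e. the out-of-fold contribution to the partial
    likelihood of the model fitted without the fold. Returns the path fitted
    on the full data together with the lambda minimizing the mean deviance.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} subjects, got {n}")
    ages = np.asarray(event_ages, dtype=float)
    ev = np.asarray(event_flags, dtype=bool)
    w = _normalized_weights(weights, n)

    path = fit_lasso_path(
        X, ages, ev, weights=w, penalty_mask=penalty_mask,
        n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio,
        tol=tol, max_irls=max_irls,
    )
    rng = np.random.default_rng(seed)
    fold_ids = _make_folds(rng, n, k, ev)

    dev = np.empty((k, len(path.lambdas)))
    for f in range(k):
        tr = fold_ids != f
        sub = fit_lasso_path(
            X[tr], ages[tr], ev[tr], weights=w[tr],
            penalty_mask=penalty_mask, lambdas=path.lambdas,
            tol=tol, max_irls=max_irls,
        )
        for j in range(len(path.lambdas)):
            b = sub.coefs[j]
            ll_all = cox_partial_loglik(b, X, ages, ev, weights=w)
            ll_tr = cox_partial_loglik(b, X[tr], ages[tr], ev[tr], weights=w[tr])
            dev[f, j] = -2.0 * (ll_all - ll_tr)

    mean_dev = dev.mean(axis=0)
    se_dev = dev.std(axis=0, ddof=1) / np.sqrt(k)
    imin = int(np.argmin(mean_dev))
    cv = CVResult(
        lambdas=path.lambdas,
        mean_deviance=mean_dev,
        se_deviance=se_dev,
        lambda_min=float(path.lambdas[imin]),
        lambda_min_index=imin,
        fold_ids=fold_ids,
    )
    return path, cv


@dataclass
class FittedModel:
    """The selected penalized Cox model: path, CV curve and chosen lambda."""

    lambda_path: np.ndarray
    cv_deviance_mean: np.ndarray
    cv_deviance_se: np.ndarray
    lambda_min: float
    betas: np.ndarray                  # coefficients at lambda_min, input scale
    penalty_mask: np.ndarray           # True for SNPs (penalized)
    feature_names: list = field(default_factory=list)

    @property
    def n_nonzero_snps(self) -> int:
        return int(np.sum((self.betas != 0) & self.penalty_mask))

    def to_dict(self):
        return {
            "lambda_path": self.lambda_path.tolist(),
            "cv_deviance_mean": self.cv_deviance_mean.tolist(),
            "cv_deviance_se": self.cv_deviance_se.tolist(),
            "lambda_min": self.lambda_min,
            "betas": self.betas.tolist(),
            "penalty_mask": self.penalty_mask.astype(int).tolist(),
            "feature_names": list(self.feature_names),
            "n_nonzero_snps": self.n_nonzero_snps,
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            lambda_path=np.asarray(d["lambda_path"], dtype=float),
            cv_deviance_mean=np.asarray(d["cv_deviance_mean"], dtype=float),
            cv_deviance_se=np.asarray(d["cv_deviance_se"], dtype=float),
            lambda_min=float(d["lambda_min"]),
            betas=np.asarray(d["betas"], dtype=float),
            penalty_mask=np.asarray(d["penalty_mask"], dtype=bool),
            feature_names=list(d["feature_names"]),
        )


def export_weights(model: FittedModel, snp_meta=None):
    """SNP weight table (snp_id, effect_allele, beta) from a fitted model.

    Only penalized predictors (SNPs) with nonzero coefficients are exported;
    principal-component coefficients never enter the score. ``snp_meta``
    supplies effect alleles by snp_id; without it the effect allele column is
    filled with the placeholder 'ALT'.
    """
    import pandas as pd

    keep = np.flatnonzero((model.betas != 0) & model.penalty_mask)
    ids = [model.feature_names[i] for i in keep]
    if snp_meta is not None:
        meta = snp_meta.set_index("snp_id")
        missing = [i for i in ids if i not in meta.index]
        if missing:
            raise KeyError(f"SNPs missing from metadata: {missing}")
        alleles = [meta.loc[i, "effect_allele"] for i in ids]
    else:
        alleles = ["ALT"] * len(ids)
    return pd.DataFrame(
        {"snp_id": ids, "effect_allele": alleles, "beta": model.betas[keep]}
    )


class LassoCoxPHS(BaseEstimator):
    """L1-regularized Cox model with cross-validated penalty selection.

    The estimator fits the full coefficient path, selects the penalty by
    k-fold cross-validated partial-likelihood deviance (minimum mean rule),
    and exposes the coefficients at the selected penalty. ``predict`` returns
    the linear predictor (the polygenic hazard score when the columns of X
    are effect-allele counts).

    Parameters
    ----------
    cv : int
        Number of cross-validation folds (0 or 1 disables CV and uses the
        smallest lambda on the path).
    n_lambda, lambda_min_ratio : path geometry.
    tol, max_irls : convergence controls for the inner solver.
    random_state : seed for the fold assignment.

    Attributes
    ----------
    coef_ : coefficients at ``lambda_min_`` on the input scale.
    lambda_path_, cv_deviance_mean_, cv_deviance_se_, lambda_min_ : CV curve.
    penalty_mask_ : which predictors carried the L1 penalty.
    n_nonzero_snps_ : penalized predictors with nonzero coefficient.
    """

    def __init__(
        self,
        cv=10,
        n_lambda=100,
        lambda_min_ratio=1e-4,
        tol=1e-8,
        max_irls=100,
        random_state=0,
    ):
        self.cv = cv
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.tol = tol
        self.max_irls = max_irls
        self.random_state = random_state

    def fit(self, X, y, sample_weight=None, penalty_free=None, feature_names=None):
        """Fit on predictors X and survival outcome y.

        ``y`` is either a structured array with (event, time) fields in that
        order (scikit-survival convention) or a tuple ``(event_flags,
        event_ages)``. ``penalty_free`` lists column indices exempt from the
        penalty (ancestry PCs).
        """
        X = np.asarray(X, dtype=float)
        event, time = _as_survival(y)
        p = X.shape[1]
        mask = np.ones(p, dtype=bool)
        if penalty_free is not None:
            mask[np.asarray(penalty_free, dtype=int)] = False
        if feature_names is None:
            feature_names = [f"x{j}" for j in range(p)]

        if self.cv and self.cv > 1:
            path, cvres = cross_validate(
                X, time, event, weights=sample_weight, penalty_mask=mask,
                k=self.cv, seed=self.random_state, n_lambda=self.n_lambda,
                lambda_min_ratio=self.lambda_min_ratio, tol=self.tol,
                max_irls=self.max_irls,
            )
            imin = cvres.lambda_min_index
            self.cv_deviance_mean_ = cvres.mean_deviance
            self.cv_deviance_se_ = cvres.se_deviance
            self.fold_ids_ = cvres.fold_ids
        else:
            path = fit_lasso_path(
                X, time, event, weights=sample_weight, penalty_mask=mask,
                n_lambda=self.n_lambda, lambda_min_ratio=self.lambda_min_ratio,
                tol=self.tol, max_irls=self.max_irls,
            )
            imin = len(path.lambdas) - 1
            self.cv_deviance_mean_ = None
            self.cv_deviance_se_ = None
            self.fold_ids_ = None

        self.path_ = path
        self.lambda_path_ = path.lambdas
        self.lambda_min_ = float(path.lambdas[imin])
        self.coef_ = path.coefs[imin]
        self.penalty_mask_ = mask
        self.feature_names_ = list(feature_names)
        self.n_nonzero_snps_ = int(np.sum((self.coef_ != 0) & mask))
        return self

    def predict(self, X):
        """Linear predictor (polygenic hazard score) for each row of X."""
        X = np.asarray(X, dtype=float)
        return X @ self.coef_

    def to_fitted_model(self) -> FittedModel:
        L = len(self.lambda_path_)
        return FittedModel(
            lambda_path=self.lambda_path_,
            cv_deviance_mean=(
                self.cv_deviance_mean_
                if self.cv_deviance_mean_ is not None
                else np.full(L, np.nan)
            ),
            cv_deviance_se=(
                self.cv_deviance_se_
                if self.cv_deviance_se_ is not None
                else np.full(L, np.nan)
            ),
            lambda_min=self.lambda_min_,
            betas=self.coef_,
            penalty_mask=self.penalty_mask_,
            feature_names=self.feature_names_,
        )


def _as_survival(y):
    """Extract (event bool array, time float array) from common encodings."""
    if isinstance(y, tuple) and len(y) == 2:
        event, time = y
        return np.asarray(event, dtype=bool), np.asarray(time, dtype=float)
    y = np.asarray(y)
    if y.dtype.names and len(y.dtype.names) == 2:
        f0, f1 = y.dtype.names
        return y[f0].astype(bool), y[f1].astype(float)
    raise TypeError(
        "y must be a (event, time) tuple or a structured array with "
        "(event, time) fields"
    )


# Re-exported so callers needing the unpenalized fit find it alongside the path
unpenalized_cox = cox_newton
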
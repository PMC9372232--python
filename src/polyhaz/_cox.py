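"""Weighted Cox partial-likelihood internals (Breslow ties).

Everything downstream — univariable SNP screening, the LASSO path, the
hazard-ratio evaluation — goes through these routines, so the conventions
are fixed here once:

* event times are ages in years, sorted ascending internally;
* tied event times share a single Breslow risk-set denominator;
* per-subject sample weights enter both the event terms and the risk sets,
  so unit weights recover the classical partial likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class ConvergenceError(RuntimeError):
    """Raised when a Cox fit diverges or fails to converge."""


@dataclass(frozen=True)
class _RiskSetIndex:
    """Sorted view of a survival sample with tie groups precomputed."""

    order: np.ndarray        # ascending-time permutation of subject indices
    group_id: np.ndarray     # tie-group index per sorted position
    n_groups: int
    event_sorted: np.ndarray
    weight_sorted: np.ndarray
    time_sorted: np.ndarray


def build_risk_index(time, event, weights=None) -> _RiskSetIndex:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    n = time.shape[0]
    if event.shape[0] != n:
        raise ValueError("time and event must have equal length")
    if np.any(~np.isfinite(time)) or np.any(time <= 0):
        raise ValueError("event ages must be positive and finite")
    if not event.any():
        raise ValueError("all subjects censored: partial likelihood undefined")
    if weights is None:
        weights = np.ones(n)
    else:
        weights = np.asarray(weights, dtype=float)
        if np.any(weights < 0) or np.any(~np.isfinite(weights)):
            raise ValueError("weights must be finite and non-negative")
    order = np.argsort(time, kind="stable")
    ts = time[order]
    new_group = np.r_[True, ts[1:] != ts[:-1]]
    group_id = np.cumsum(new_group) - 1
    return _RiskSetIndex(
        order=order,
        group_id=group_id,
        n_groups=int(group_id[-1]) + 1,
        event_sorted=event[order],
        weight_sorted=weights[order],
        time_sorted=ts,
    )


def _group_sums(values, idx: _RiskSetIndex):
    out = np.zeros(idx.n_groups)
    np.add.at(out, idx.group_id, values)
    return out


def _risk_denominators(idx: _RiskSetIndex, lp_sorted):
    """Scaled risk-set sums D_g / e^c per tie group, with the log offset c."""
    c = float(np.max(lp_sorted))
    s = idx.weight_sorted * np.exp(lp_sorted - c)
    per_group = _group_sums(s, idx)
    denom = np.cumsum(per_group[::-1])[::-1]  # suffix sums: risk set {t >= t_g}
    return s, denom, c


def breslow_loglik_sorted(idx: _RiskSetIndex, lp_sorted):
    """Partial log-likelihood for a linear predictor already in sorted order."""
    _, denom, c = _risk_denominators(idx, lp_sorted)
    ev = idx.event_sorted
    w = idx.weight_sorted
    e_g = _group_sums(np.where(ev, w, 0.0), idx)
    event_term = float(np.sum(w[ev] * lp_sorted[ev]))
    denom_term = float(np.sum(e_g * (np.log(denom) + c)))
    return event_term - denom_term


def breslow_loglik(lp, time, event, weights=None, idx: _RiskSetIndex | None = None):
    """Weighted Breslow partial log-likelihood at linear predictor ``lp``."""
    if idx is None:
        idx = build_risk_index(time, event, weights)
    lp = np.asarray(lp, dtype=float)
    return breslow_loglik_sorted(idx, lp[idx.order])


def lp_grad_hess(idx: _RiskSetIndex, lp_sorted):
    """Gradient and (diagonal) negative-Hessian of the partial log-likelihood
    with respect to the per-subject linear predictor, in sorted order.

    These are the IRLS working quantities for the coordinate-descent solver.
    """
    s, denom, _ = _risk_denominators(idx, lp_sorted)
    ev = idx.event_sorted
    w = idx.weight_sorted
    e_g = _group_sums(np.where(ev, w, 0.0), idx)
    a_g = np.cumsum(e_g / denom)            # prefix over event groups t_g <= t
    b_g = np.cumsum(e_g / denom**2)
    a_i = a_g[idx.group_id]
    b_i = b_g[idx.group_id]
    grad = np.where(ev, w, 0.0) - s * a_i
    hess = s * a_i - s**2 * b_i
    return grad, hess


def cox_loglik_grad_info(X, beta, idx: _RiskSetIndex):
    """Log-likelihood, score vector and observed information for beta."""
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    Xs = X[idx.order]
    lps = Xs @ beta
    s, denom, c = _risk_denominators(idx, lps)
    ev = idx.event_sorted
    w = idx.weight_sorted
    e_g = _group_sums(np.where(ev, w, 0.0), idx)

    ll = float(np.sum(w[ev] * lps[ev]) - np.sum(e_g * (np.log(denom) + c)))

    sx = Xs * s[:, None]
    # suffix sums of s*x per group -> S1_g (p,) per group
    p = X.shape[1]
    s1 = np.zeros((idx.n_groups, p))
    np.add.at(s1, idx.group_id, sx)
    s1 = np.cumsum(s1[::-1], axis=0)[::-1]

    sxx = np.einsum("ij,ik->ijk", Xs, Xs) * s[:, None, None]
    s2 = np.zeros((idx.n_groups, p, p))
    np.add.at(s2, idx.group_id, sxx)
    s2 = np.cumsum(s2[::-1], axis=0)[::-1]

    r = s1 / denom[:, None]                       # E[x | risk set g]
    grad = np.sum(np.where(ev, w, 0.0)[:, None] * Xs, axis=0) - e_g @ r
    info = np.einsum("g,gjk->jk", e_g, s2 / denom[:, None, None])
    info -= np.einsum("g,gj,gk->jk", e_g, r, r)
    return ll, grad, info


@dataclass
class CoxFit:
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    n_iter: int

    @property
    def z(self):
        return self.beta / self.se

    @property
    def wald_p(self):
        from scipy.stats import norm

        return 2.0 * norm.sf(np.abs(self.z))


_DIVERGE_BOUND = 10.0  # |beta| per predictor SD beyond which the MLE is at infinity


def cox_newton(X, time, event, weights=None, tol=1e-9, max_iter=100) -> CoxFit:
    """Unpenalized weighted Cox fit by Newton–Raphson with step halving.

    Predictors are standardized internally for conditioning; coefficients and
    standard errors are returned on the original scale. Monotone-likelihood
    divergence (a coefficient running to infinity) raises ``ConvergenceError``
    rather than returning a silent boundary estimate.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant predictor column: Cox coefficient undefined")
    mu = X.mean(axis=0)
    Xs = (X - mu) / sd

    idx = build_risk_index(time, event, weights)
    beta = np.zeros(p)
    ll_prev, grad, info = cox_loglik_grad_info(Xs, beta, idx)
    ll_null = ll_prev
    scale = max(1.0, abs(ll_null))
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        # backtracking: partial likelihood is concave, full step can overshoot
        factor = 1.0
        for _ in range(40):
            cand = beta + factor * step
            ll, g2, i2 = cox_loglik_grad_info(Xs, cand, idx)
            if np.isfinite(ll) and ll >= ll_prev - 1e-12 * scale:
                break
            factor *= 0.5
        else:
            raise ConvergenceError("step halving failed to improve likelihood")
        beta, grad, info = cand, g2, i2
        if np.any(np.abs(beta) > _DIVERGE_BOUND):
            raise ConvergenceError(
                "coefficient diverging (monotone likelihood / separation); "
                f"|beta|_std > {_DIVERGE_BOUND}"
            )
        if abs(ll - ll_prev) <= tol * scale and np.max(np.abs(grad)) <= 1e-6 * scale:
            ll_prev = ll
            break
        ll_prev = ll
    else:
        raise ConvergenceError(f"no convergence in {max_iter} Newton iterations")

    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    return CoxFit(
        beta=beta / sd,
        se=se / sd,
        loglik=ll_prev,
        loglik_null=ll_null,
        n_iter=it,
    )
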
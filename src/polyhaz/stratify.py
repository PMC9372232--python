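"""Hazard-ratio risk stratification and the family-history comparison.

Hazard ratios between percentile bands are obtained from a single weighted
Cox fit of the endpoint on the continuous PHS, contrasted through the
reference band means: HR_A/B = exp(beta * (m_A - m_B)). This reproduces the
multiplicative structure HR_80/20 = HR_80/50 / HR_20/50 exactly within every
bootstrap replicate. Case enrichment is corrected by inverse-probability
sample weights that restore a configurable population prevalence.

Endpoints:

* ``any``: every case is an event at its diagnosis age.
* ``significant``: clinically significant cases are events at diagnosis
  age; all other subjects (including non-significant cases) are censored at
  their recorded age.
* ``fatal``: disease deaths are events at death age; everyone else is
  censored at last contact (death age if present, else event age).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from ._cox import cox_newton
from .scoring import PercentileReference

__all__ = [
    "sample_weights",
    "endpoint_survival",
    "cox_beta_phs",
    "band_hr",
    "hr_report",
    "family_history_comparison",
    "HRReport",
    "FamilyHistoryComparison",
    "P_FLOOR",
]

P_FLOOR = 1e-16  # reported p-values are truncated below this

ENDPOINTS = ("any", "significant", "fatal")


def sample_weights(phen: pd.DataFrame, target_prevalence: float) -> np.ndarray:
    """Inverse-probability weights correcting case oversampling.

    Controls get weight 1; cases get ``(pi/(1-pi)) * (N_controls/N_cases)``
    so the weighted case fraction equals the population prevalence ``pi``.
    """
    if not 0 < target_prevalence < 1:
        raise ValueError("target prevalence must lie in (0,1)")
    is_case = (phen["status"] == "case").to_numpy()
    n_case = int(is_case.sum())
    n_ctrl = int((~is_case).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("need both cases and controls to compute weights")
    pi = target_prevalence
    w_case = (pi / (1 - pi)) * (n_ctrl / n_case)
    return np.where(is_case, w_case, 1.0)


def endpoint_survival(phen: pd.DataFrame, endpoint: str):
    """(event flags, event/censoring ages) for a named endpoint."""
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}; expected {ENDPOINTS}")
    is_case = (phen["status"] == "case").to_numpy()
    age = phen["event_age"].to_numpy(dtype=float)
    if endpoint == "any":
        return is_case, age
    if endpoint == "significant":
        sig = phen["significant"].to_numpy(dtype=float)
        event = is_case & (sig == 1.0)
        return event, age
    # fatal: events at death age, others censored at last contact
    fatal = phen["fatal"].to_numpy(dtype=float) == 1.0
    death = phen["death_age"].to_numpy(dtype=float)
    time = np.where(fatal, death, np.where(np.isnan(death), age, death))
    return fatal, time


def cox_beta_phs(scores, phen: pd.DataFrame, endpoint: str, weights=None):
    """Weighted Cox fit of the endpoint's time-to-event on the continuous
    PHS. Returns (beta, SE)."""
    event, time = endpoint_survival(phen, endpoint)
    if not event.any():
        raise ValueError(f"no events for endpoint {endpoint!r}")
    fit = cox_newton(np.asarray(scores, dtype=float)[:, None], time, event,
                     weights=weights)
    return float(fit.beta[0]), float(fit.se[0])


_BAND_MEAN_KEY = {"bottom20": "bottom20", "mid40_60": "mid40_60",
                  "top20": "top20", "top5": "top5"}


def band_hr(beta: float, ref: PercentileReference, band_a: str, band_b: str) -> float:
    """HR between percentile bands: exp(beta * (m_A - m_B)) with the young-
    control reference band means."""
    m_a = ref.band_means_[_BAND_MEAN_KEY[band_a]]
    m_b = ref.band_means_[_BAND_MEAN_KEY[band_b]]
    if m_a == m_b and band_a != band_b:
        warnings.warn(
            "degenerate reference: equal band means, HR = 1", UserWarning,
            stacklevel=2,
        )
    return float(np.exp(beta * (m_a - m_b)))


def _four_band_hrs(beta: float, ref: PercentileReference) -> dict:
    return {
        "hr_20_50": band_hr(beta, ref, "bottom20", "mid40_60"),
        "hr_80_50": band_hr(beta, ref, "top20", "mid40_60"),
        "hr_95_50": band_hr(beta, ref, "top5", "mid40_60"),
        "hr_80_20": band_hr(beta, ref, "top20", "bottom20"),
    }


@dataclass
class HRReport:
    """Sample-weight-corrected band hazard ratios with bootstrap CIs."""

    endpoint: str
    hrs: dict            # name -> (mean, ci_low, ci_high)
    n_boot: int
    seed: int
    replicates: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self):
        return {
            "endpoint": self.endpoint,
            "hrs": {k: list(map(float, v)) for k, v in self.hrs.items()},
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


def hr_report(
    scores,
    phen: pd.DataFrame,
    ref: PercentileReference,
    endpoint: str,
    target_prevalence: float,
    n_boot: int = 1000,
    seed: int = 0,
    max_retry: int = 100,
) -> HRReport:
    """Bootstrap band hazard ratios, stratified by case status.

    Each replicate resamples cases and controls with replacement (separately,
    preserving the design ratio), recomputes the sample weights and the
    weighted Cox beta, and converts it into the four band HRs. Reported are
    the replicate means with 2.5-97.5 percentile CIs.
    """
    scores = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    is_case = (phen["status"] == "case").to_numpy()
    case_ix = np.flatnonzero(is_case)
    ctrl_ix = np.flatnonzero(~is_case)
    if len(case_ix) == 0 or len(ctrl_ix) == 0:
        raise ValueError("need both cases and controls")

    rows = []
    for _ in range(n_boot):
        for attempt in range(max_retry):
            take = np.concatenate(
                [
                    rng.choice(case_ix, size=len(case_ix), replace=True),
                    rng.choice(ctrl_ix, size=len(ctrl_ix), replace=True),
                ]
            )
            sub = phen.iloc[take].reset_index(drop=True)
            sub = sub.assign(subject_id=[f"B{i}" for i in range(len(sub))])
            event, _ = endpoint_survival(sub, endpoint)
            if event.any():
                break
        else:
            raise RuntimeError(
                f"no events for endpoint {endpoint!r} in {max_retry} redraws"
            )
        w = sample_weights(sub, target_prevalence)
        beta, _ = cox_beta_phs(scores[take], sub, endpoint, weights=w)
        rows.append(_four_band_hrs(beta, ref))

    reps = pd.DataFrame(rows)
    hrs = {
        k: (
            float(reps[k].mean()),
            float(np.percentile(reps[k], 2.5)),
            float(np.percentile(reps[k], 97.5)),
        )
        for k in reps.columns
    }
    return HRReport(endpoint=endpoint, hrs=hrs, n_boot=n_boot, seed=seed,
                    replicates=reps)


def _format_p(p: float) -> str:
    return "<1e-16" if p < P_FLOOR else f"{p:.3g}"


@dataclass
class FamilyHistoryComparison:
    """Multivariable FH + PHS Cox model against FH alone (one endpoint)."""

    endpoint: str
    beta_phs: float
    z_phs: float
    p_phs: float
    hr_phs: float            # reported as HR_80/20
    beta_fh: float
    z_fh: float
    p_fh: float
    hr_fh: float             # exp(beta_fh)
    lrt_stat: float
    lrt_p: float
    alpha: float
    n_used: int

    @property
    def p_phs_str(self):
        return _format_p(self.p_phs)

    @property
    def p_fh_str(self):
        return _format_p(self.p_fh)

    @property
    def lrt_p_str(self):
        return _format_p(self.lrt_p)

    def to_dict(self):
        d = {
            k: getattr(self, k)
            for k in (
                "endpoint", "beta_phs", "z_phs", "hr_phs",
                "beta_fh", "z_fh", "hr_fh", "lrt_stat", "alpha", "n_used",
            )
        }
        d["p_phs"] = self.p_phs_str
        d["p_fh"] = self.p_fh_str
        d["lrt_p"] = self.lrt_p_str
        return d


def family_history_comparison(
    scores,
    phen: pd.DataFrame,
    endpoint: str,
    ref: PercentileReference,
    weights=None,
    alpha: float = 0.01,
) -> FamilyHistoryComparison:
    """Does adding the PHS to family history improve the Cox model?

    Restricted to subjects with known family history. Fits
    Cox(endpoint ~ FH) and Cox(endpoint ~ FH + PHS), compares them with a
    1-df likelihood-ratio test, and reports per-variable Wald statistics:
    the PHS hazard ratio as HR_80/20 (top vs bottom quintile of the
    reference), the family-history one as exp(beta_FH). p-values are
    two-sided and truncated below 1e-16.
    """
    scores = np.asarray(scores, dtype=float)
    known = (phen["family_history"] != "unknown").to_numpy()
    if not known.any():
        raise ValueError("no subjects with known family history")
    sub = phen.loc[known].reset_index(drop=True)
    s = scores[known]
    w = None if weights is None else np.asarray(weights, dtype=float)[known]
    fh = (sub["family_history"] == "yes").to_numpy(dtype=float)
    event, time = endpoint_survival(sub, endpoint)
    if not event.any():
        raise ValueError(f"no events for endpoint {endpoint!r} among known-FH")

    if fh.std() == 0:
        raise ValueError("family history constant among known-FH subjects")
    reduced = cox_newton(fh[:, None], time, event, weights=w)
    if s.std() == 0:
        # PHS carries no information: the full model equals the reduced one
        full_ll = reduced.loglik
        beta_phs = z_phs = 0.0
        p_phs = 1.0
        beta_fh, se_fh = float(reduced.beta[0]), float(reduced.se[0])
        z_fh = beta_fh / se_fh
        p_fh = float(reduced.wald_p[0])
    else:
        full = cox_newton(np.column_stack([fh, s]), time, event, weights=w)
        full_ll = full.loglik
        beta_fh, z_fh, p_fh = float(full.beta[0]), float(full.z[0]), float(full.wald_p[0])
        beta_phs, z_phs, p_phs = float(full.beta[1]), float(full.z[1]), float(full.wald_p[1])

    lrt = max(0.0, 2.0 * (full_ll - reduced.loglik))
    lrt_p = float(chi2.sf(lrt, df=1)) if lrt > 0 else 1.0
    hr_phs = band_hr(beta_phs, ref, "top20", "bottom20")
    return FamilyHistoryComparison(
        endpoint=endpoint,
        beta_phs=beta_phs,
        z_phs=z_phs,
        p_phs=max(p_phs, 0.0),
        hr_phs=hr_phs,
        beta_fh=beta_fh,
        z_fh=z_fh,
        p_fh=max(p_fh, 0.0),
        hr_fh=float(np.exp(beta_fh)),
        lrt_stat=lrt,
        lrt_p=lrt_p,
        alpha=alpha,
        n_used=int(known.sum()),
    )
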
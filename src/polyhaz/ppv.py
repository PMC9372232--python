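"""Positive predictive value of PSA screening, with and without genetic
risk stratification.

PPV is the fraction of PSA-positive subjects whose biopsy shows clinically
significant disease. The stratified variants condition additionally on
membership in the top 20% (PPV_80) or top 5% (PPV_95) of the polygenic
hazard score, using the training young-control percentile reference.
Confidence intervals come from a bootstrap over PSA-positive subjects that
resamples cases and controls separately, preserving the configured
case:control ratio (1:2 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scoring import PercentileReference

__all__ = ["ppv_point", "ppv_bootstrap", "PPVReport", "UndefinedPPVError"]


class UndefinedPPVError(ValueError):
    """PPV requested on an empty subset of PSA-positive subjects."""


def ppv_point(subset: pd.DataFrame) -> float:
    """Proportion of the PSA-positive subset with significant biopsy."""
    if len(subset) == 0:
        raise UndefinedPPVError("no PSA-positive subjects: PPV undefined")
    biopsy = subset["biopsy_significant"].to_numpy(dtype=float)
    if np.isnan(biopsy).any():
        raise ValueError("biopsy outcome unknown for some subjects in subset")
    return float((biopsy == 1.0).mean())


@dataclass
class PPVReport:
    """Bootstrap PPV estimates: overall and within top PHS bands."""

    ppv: dict                  # name -> (mean, ci_low, ci_high)
    plug_in: dict              # name -> full-sample point estimate (or nan)
    n_psa_positive: int
    n_boot: int
    ratio: float               # controls per case among screen-positives
    seed: int
    warnings: list = field(default_factory=list)
    replicates: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self):
        return {
            "ppv": {k: list(map(float, v)) for k, v in self.ppv.items()},
            "plug_in": {k: float(v) for k, v in self.plug_in.items()},
            "n_psa_positive": self.n_psa_positive,
            "n_boot": self.n_boot,
            "ratio": self.ratio,
            "seed": self.seed,
            "warnings": list(self.warnings),
        }


def _ppv_of(biopsy: np.ndarray, member: np.ndarray) -> float:
    if not member.any():
        return np.nan
    return float((biopsy[member] == 1.0).mean())


def ppv_bootstrap(
    phen: pd.DataFrame,
    scores,
    ref: PercentileReference,
    n_boot: int = 1000,
    ratio: float = 2.0,
    seed: int = 0,
) -> PPVReport:
    """Stratified bootstrap of PPV, PPV_80 and PPV_95.

    Subjects enter if PSA-positive with a known biopsy outcome (controls
    with unknown biopsy are excluded up front). Each replicate resamples
    PSA-positive cases with replacement and ``round(ratio * n_cases)``
    controls with replacement; the point estimate is the replicate mean and
    the CI the 2.5-97.5 percentile band. A band empty in more than half of
    the replicates is recorded as a warning on the report.
    """
    scores = np.asarray(scores, dtype=float)
    pos = (phen["psa_positive"].to_numpy(dtype=float) == 1.0)
    known = ~np.isnan(phen["biopsy_significant"].to_numpy(dtype=float))
    pool = pos & known
    if not pool.any():
        raise UndefinedPPVError("no PSA-positive subjects with biopsy outcome")
    sub = phen.loc[pool]
    s = scores[pool]
    biopsy = sub["biopsy_significant"].to_numpy(dtype=float)
    is_case = (sub["status"] == "case").to_numpy()
    case_ix = np.flatnonzero(is_case)
    ctrl_ix = np.flatnonzero(~is_case)
    warnings_ = []
    n_case = len(case_ix)
    if len(ctrl_ix) == 0:
        # degenerate screen: every PSA-positive subject is a case; resample
        # the single stratum and note that the ratio cannot be enforced
        n_ctrl = 0
        warnings_.append("no PSA-positive controls: ratio not enforced")
    else:
        n_ctrl = int(round(ratio * n_case))
    if n_case == 0:
        n_ctrl = len(ctrl_ix)
        warnings_.append("no PSA-positive cases: ratio not enforced")

    in80 = ref.in_band(s, "top20")
    in95 = ref.in_band(s, "top5")
    plug_in = {
        "ppv_overall": _ppv_of(biopsy, np.ones(len(s), dtype=bool)),
        "ppv_80": _ppv_of(biopsy, in80),
        "ppv_95": _ppv_of(biopsy, in95),
    }

    rng = np.random.default_rng(seed)
    rows = []
    empty = {"ppv_80": 0, "ppv_95": 0}
    for _ in range(n_boot):
        parts = []
        if n_case:
            parts.append(rng.choice(case_ix, size=n_case, replace=True))
        if n_ctrl:
            parts.append(rng.choice(ctrl_ix, size=n_ctrl, replace=True))
        take = np.concatenate(parts)
        b = biopsy[take]
        m80 = in80[take]
        m95 = in95[take]
        row = {
            "ppv_overall": float((b == 1.0).mean()),
            "ppv_80": _ppv_of(b, m80),
            "ppv_95": _ppv_of(b, m95),
        }
        for k in ("ppv_80", "ppv_95"):
            if np.isnan(row[k]):
                empty[k] += 1
        rows.append(row)
    reps = pd.DataFrame(rows)

    warnings_ += [
        f"{k} band empty in {v}/{n_boot} bootstrap replicates"
        for k, v in empty.items()
        if v > n_boot / 2
    ]
    ppv = {}
    for k in reps.columns:
        col = reps[k].dropna()
        if len(col) == 0:
            ppv[k] = (np.nan, np.nan, np.nan)
        else:
            ppv[k] = (
                float(col.mean()),
                float(np.percentile(col, 2.5)),
                float(np.percentile(col, 97.5)),
            )
    return PPVReport(
        ppv=ppv,
        plug_in=plug_in,
        n_psa_positive=int(pool.sum()),
        n_boot=n_boot,
        ratio=ratio,
        seed=seed,
        warnings=warnings_,
        replicates=reps,
    )
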
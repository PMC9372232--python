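"""Polygenic hazard score computation and percentile reference machinery.

The score of a subject is the Cox linear predictor sum(beta_i * x_i) over
the weight table's SNPs, with x_i the effect-allele count. If a weight
table's effect allele matches the genotype file's *other* allele, the count
is flipped to 2 - x before weighting (standard polygenic-score practice);
any other allele mismatch is an error. Missing genotypes contribute via
mean imputation, 2 * effect-allele frequency.

Percentiles of genetic risk are defined once, on young controls (age below
a cutoff, by default 70) of the training set: thresholds are type-1
(inverted empirical CDF) quantiles without interpolation, and each band's
mean score on that same reference population is what converts a fitted Cox
coefficient into a between-band hazard ratio downstream.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import GenotypeMatrix, validate_weights

__all__ = [
    "compute_phs",
    "build_percentile_reference",
    "assign_band",
    "PercentileReference",
    "DegenerateReferenceWarning",
]


class DegenerateReferenceWarning(UserWarning):
    """Reference scores are (nearly) constant; bands are not meaningful."""


def compute_phs(g: GenotypeMatrix, weights: pd.DataFrame) -> np.ndarray:
    """Per-subject polygenic hazard score sum(beta_i * x_i).

    Every weight-table SNP must be resolvable in the genotype data by id,
    with its effect allele equal to either the genotype effect allele
    (counted as-is) or the other allele (count flipped to 2 - x).
    """
    validate_weights(weights)
    meta = g.snp_meta.set_index("snp_id")
    missing = [s for s in weights["snp_id"] if s not in meta.index]
    if missing:
        raise KeyError(f"weight-table SNPs absent from genotypes: {missing}")

    col_of = {s: k for k, s in enumerate(g.snp_meta["snp_id"])}
    scores = np.zeros(g.n_subjects)
    for _, row in weights.iterrows():
        sid, allele, beta = row["snp_id"], row["effect_allele"], float(row["beta"])
        j = col_of[sid]
        eff = meta.loc[sid, "effect_allele"]
        oth = meta.loc[sid, "other_allele"]
        x = g.counts[:, j]
        if allele == eff:
            pass
        elif allele == oth:
            x = 2.0 - x
        else:
            raise ValueError(
                f"SNP {sid}: weight effect allele {allele!r} matches neither "
                f"genotype allele ({eff!r}/{oth!r})"
            )
        freq = meta.loc[sid, "freq"]
        if np.isnan(x).any():
            if np.isnan(freq):
                freq = np.nanmean(x) / 2.0
            elif allele == oth:
                freq = 1.0 - freq
            x = np.where(np.isnan(x), 2.0 * freq, x)
        scores += beta * x
    return scores


class PercentileReference(BaseEstimator):
    """Centile thresholds and band means of the PHS on a reference population.

    Bands follow the half-open convention [low, high), except the top band
    which is closed above; a score in the top 5% is simultaneously in the
    top 20%. The "middle 40%" band is percentiles 30-70.

    Attributes (after fit)
    ----------------------
    thresholds_ : dict centile -> score threshold for {20, 30, 70, 80, 95}.
    band_means_ : dict band -> mean reference score, bands
        ``bottom20`` [0,20), ``mid40_60`` [30,70), ``top20`` [80,100],
        ``top5`` [95,100].
    n_reference_ : reference population size.
    """

    CENTILES = (20, 30, 70, 80, 95)

    def __init__(self, source: str = "training controls, age < 70"):
        self.source = source

    def fit(self, scores):
        scores = np.asarray(scores, dtype=float)
        if scores.size == 0:
            raise ValueError("empty reference population")
        if scores.size < 100:
            warnings.warn(
                f"only {scores.size} reference subjects; percentile "
                "thresholds will be unstable (>= 100 recommended)",
                UserWarning,
                stacklevel=2,
            )
        if np.ptp(scores) == 0:
            warnings.warn(
                "all reference scores identical; bands are degenerate",
                DegenerateReferenceWarning,
                stacklevel=2,
            )
        self.thresholds_ = {
            c: float(np.quantile(scores, c / 100.0, method="inverted_cdf"))
            for c in self.CENTILES
        }
        t = self.thresholds_
        bands = {
            "bottom20": scores < t[20],
            "mid40_60": (scores >= t[30]) & (scores < t[70]),
            "top20": scores >= t[80],
            "top5": scores >= t[95],
        }
        self.band_means_ = {}
        for name, mask in bands.items():
            self.band_means_[name] = (
                float(scores[mask].mean()) if mask.any() else float("nan")
            )
        self.n_reference_ = int(scores.size)
        return self

    def assign(self, scores):
        """Band labels per score: one of bottom20 / mid40_60 / top20 / top5 /
        other, where top5 supersedes top20 in the single-label output."""
        scores = np.asarray(scores, dtype=float)
        t = self.thresholds_
        out = np.full(scores.shape, "other", dtype=object)
        out[scores < t[20]] = "bottom20"
        out[(scores >= t[30]) & (scores < t[70])] = "mid40_60"
        out[scores >= t[80]] = "top20"
        out[scores >= t[95]] = "top5"
        return out

    def in_band(self, scores, band: str):
        """Boolean membership, honouring the overlap of top5 with top20."""
        scores = np.asarray(scores, dtype=float)
        t = self.thresholds_
        if band == "bottom20":
            return scores < t[20]
        if band == "mid40_60":
            return (scores >= t[30]) & (scores < t[70])
        if band == "top20":
            return scores >= t[80]
        if band == "top5":
            return scores >= t[95]
        raise KeyError(f"unknown band {band!r}")

    def to_json(self, path=None):
        d = {
            "source": self.source,
            "thresholds": {str(k): v for k, v in self.thresholds_.items()},
            "band_means": self.band_means_,
            "n_reference": self.n_reference_,
        }
        text = json.dumps(d, sort_keys=True, indent=2)
        if path is not None:
            with open(path, "w", newline="\n") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path_or_text):
        try:
            d = json.loads(path_or_text)
        except (json.JSONDecodeError, TypeError):
            with open(path_or_text) as fh:
                d = json.load(fh)
        ref = cls(source=d["source"])
        ref.thresholds_ = {int(k): float(v) for k, v in d["thresholds"].items()}
        ref.band_means_ = {k: float(v) for k, v in d["band_means"].items()}
        ref.n_reference_ = int(d["n_reference"])
        return ref


def build_percentile_reference(
    scores,
    phen: pd.DataFrame | None = None,
    max_age: float = 70.0,
) -> PercentileReference:
    """Percentile reference from training-set young controls.

    When ``phen`` is given, the reference population is restricted to
    controls with last-follow-up age below ``max_age``; otherwise all
    supplied scores are used as-is.
    """
    scores = np.asarray(scores, dtype=float)
    if phen is not None:
        keep = (
            (phen["status"] == "control") & (phen["event_age"] < max_age)
        ).to_numpy()
        scores = scores[keep]
    src = f"training controls, age < {max_age:g}"
    return PercentileReference(source=src).fit(scores)


def assign_band(score, ref: PercentileReference):
    """Band label(s) for one score: list of labels among
    {bottom20, mid40_60, top20, top5, other}; a score at or above the 95th
    threshold is both top20 and top5."""
    labels = [
        b for b in ("bottom20", "mid40_60", "top20", "top5")
        if bool(ref.in_band(np.array([score]), b)[0])
    ]
    return labels if labels else ["other"]
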
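"""Correlation-based SNP pruning.

Among candidate SNPs, pairs with genotypic r2 above a threshold are reduced
to one member: each SNP of a flagged pair is tested in a univariable Cox
model for association with age at diagnosis, and the member with the larger
Wald p-value is dropped. Pairs are processed in ascending order of the
smaller p-value within the pair, and a SNP that has already been removed
cannot trigger further removals — this greedy order makes the outcome of
correlation chains deterministic. Unpaired SNPs are always kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._cox import cox_newton
from .cohort import GenotypeMatrix

__all__ = [
    "pairwise_r2",
    "univariable_cox_p",
    "prune",
    "PruningReport",
    "CorrelationPruner",
]


def pairwise_r2(g: GenotypeMatrix, i: int, j: int) -> float:
    """Squared Pearson correlation of allele counts over pairwise-complete
    subjects. Requires >= 3 complete pairs and non-constant columns."""
    x = g.counts[:, i]
    y = g.counts[:, j]
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 3:
        raise ValueError(
            f"fewer than 3 pairwise-complete subjects for SNPs {i}, {j}"
        )
    x, y = x[ok], y[ok]
    if x.std() == 0 or y.std() == 0:
        raise ValueError(
            f"zero genotype variance (SNP {i if x.std() == 0 else j}): "
            "correlation undefined"
        )
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def univariable_cox_p(genotype_column, phen: pd.DataFrame) -> float:
    """Two-sided Wald p-value of the allele count in a univariable Cox model
    of age at diagnosis (cases are events; controls censored at last
    follow-up). Missing genotypes are mean-imputed."""
    x = np.asarray(genotype_column, dtype=float)
    if np.isnan(x).any():
        x = np.where(np.isnan(x), np.nanmean(x), x)
    event = (phen["status"] == "case").to_numpy()
    if not event.any():
        raise ValueError("no events: univariable Cox p undefined")
    time = phen["event_age"].to_numpy(dtype=float)
    fit = cox_newton(x[:, None], time, event)
    return float(fit.wald_p[0])


@dataclass
class PruningReport:
    """Outcome of pruning: (removed, kept, r2, p_removed, p_kept) per pair."""

    removed: list = field(default_factory=list)
    kept_ids: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.removed,
            columns=["removed_id", "kept_id", "r2", "p_removed", "p_kept"],
        )


def _correlated_pairs(counts: np.ndarray, threshold: float):
    """All index pairs (i < j) with genotypic r2 above the threshold."""
    mask = np.isnan(counts)
    X = np.where(mask, 0.0, counts)
    if mask.any():
        # pairwise-complete correlation, brute force on the flagged columns
        p = counts.shape[1]
        out = []
        for i in range(p):
            for j in range(i + 1, p):
                ok = ~mask[:, i] & ~mask[:, j]
                xi, xj = counts[ok, i], counts[ok, j]
                if ok.sum() < 3 or xi.std() == 0 or xj.std() == 0:
                    continue
                r = np.corrcoef(xi, xj)[0, 1]
                if r * r > threshold:
                    out.append((i, j, float(r * r)))
        return out
    sd = X.std(axis=0)
    keep = sd > 0
    corr = np.corrcoef(X, rowvar=False)
    r2 = corr**2
    iu, ju = np.triu_indices(counts.shape[1], k=1)
    hits = (r2[iu, ju] > threshold) & keep[iu] & keep[ju]
    return [(int(i), int(j), float(r2[i, j])) for i, j in zip(iu[hits], ju[hits])]


def prune(
    g: GenotypeMatrix,
    phen: pd.DataFrame,
    threshold: float = 0.95,
):
    """Remove the weaker member of every highly correlated SNP pair.

    Returns the pruned :class:`GenotypeMatrix` and a :class:`PruningReport`.
    Ties on equal p-values keep the lexicographically smaller snp_id.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    ids = g.snp_ids
    pairs = _correlated_pairs(g.counts, threshold)
    involved = sorted({i for pr in pairs for i in pr[:2]})
    pvals = {}
    for i in involved:
        pvals[i] = univariable_cox_p(g.counts[:, i], phen)

    # ascending order of the within-pair minimum p-value; id-based secondary
    # key so the outcome is invariant to column order
    pairs.sort(
        key=lambda pr: (
            min(pvals[pr[0]], pvals[pr[1]]),
            tuple(sorted((ids[pr[0]], ids[pr[1]]))),
        )
    )
    removed_set = set()
    report = PruningReport()
    for i, j, r2 in pairs:
        if i in removed_set or j in removed_set:
            continue  # an eliminated SNP cannot cause further removals
        pi, pj = pvals[i], pvals[j]
        if pi > pj or (pi == pj and ids[i] > ids[j]):
            drop, keep = i, j
        else:
            drop, keep = j, i
        removed_set.add(drop)
        report.removed.append(
            (ids[drop], ids[keep], r2, pvals[drop], pvals[keep])
        )
    kept = [s for k, s in enumerate(ids) if k not in removed_set]
    report.kept_ids = kept
    return g.select_snps(kept), report


class CorrelationPruner(BaseEstimator, TransformerMixin):
    """Transformer wrapper over :func:`prune` for array pipelines.

    fit(X, y) expects allele counts X and survival y as an ``(event, time)``
    tuple or structured array; transform(X) keeps the surviving columns.

    Attributes
    ----------
    kept_idx_ : column indices that survive pruning.
    report_ : list of (removed_idx, kept_idx, r2, p_removed, p_kept).
    """

    def __init__(self, threshold: float = 0.95):
        self.threshold = threshold

    def fit(self, X, y):
        from .lasso_cox import _as_survival

        X = np.asarray(X, dtype=float)
        event, time = _as_survival(y)
        meta = pd.DataFrame(
            {
                "snp_id": [f"c{j:05d}" for j in range(X.shape[1])],
                "chrom": ["."] * X.shape[1],
                "pos": np.arange(1, X.shape[1] + 1),
                "effect_allele": ["ALT"] * X.shape[1],
                "other_allele": ["REF"] * X.shape[1],
                "freq": [np.nan] * X.shape[1],
            }
        )
        g = GenotypeMatrix(
            subject_ids=np.array([f"S{i}" for i in range(X.shape[0])], dtype=object),
            snp_meta=meta,
            counts=X,
        )
        phen = pd.DataFrame(
            {
                "status": np.where(event, "case", "control"),
                "event_age": time,
            }
        )
        pruned, rep = prune(g, phen, threshold=self.threshold)
        name_to_idx = {s: k for k, s in enumerate(meta["snp_id"])}
        self.kept_idx_ = np.array([name_to_idx[s] for s in rep.kept_ids])
        self.report_ = [
            (name_to_idx[a], name_to_idx[b], r2, pa, pb)
            for a, b, r2, pa, pb in rep.removed
        ]
        return self

    def transform(self, X):
        X = np.asarray(X)
        return X[:, self.kept_idx_]
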
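"""In-memory containers: genotype matrix and phenotype table schema.

The phenotype table is a plain pandas DataFrame with a fixed column set
(validated by :func:`validate_phenotypes`); the genotype matrix couples a
subjects x SNPs allele-count array with per-SNP metadata. Missing genotype
calls are NaN entries; missing phenotype fields are NaN (numeric) or
"unknown" (family history).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PHENOTYPE_COLUMNS = [
    "subject_id",
    "status",
    "event_age",
    "significant",
    "fatal",
    "death_age",
    "family_history",
    "psa_positive",
    "biopsy_significant",
    "pc1",
    "pc2",
    "pc3",
    "pc4",
]

SNP_META_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "freq",
]


class PhenotypeValidationError(ValueError):
    """Raised when a phenotype table violates the schema invariants."""


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs effect-allele count matrix with SNP metadata.

    ``counts`` entries are 0/1/2 or NaN for a missing call. ``snp_meta`` has
    columns (snp_id, chrom, pos, effect_allele, other_allele, freq); the
    effect allele is the counted allele (the VCF ALT).
    """

    subject_ids: np.ndarray
    snp_meta: pd.DataFrame
    counts: np.ndarray

    def __post_init__(self):
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.counts = np.asarray(self.counts, dtype=float)
        self.validate()

    def validate(self):
        n, p = self.counts.shape
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match count rows")
        if len(self.snp_meta) != p:
            raise ValueError("snp_meta length does not match count columns")
        if len(set(self.subject_ids)) != n:
            raise ValueError("duplicate subject ids")
        ids = self.snp_meta["snp_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].tolist()
            raise ValueError(f"duplicate SNP ids: {dup}")
        vals = self.counts[~np.isnan(self.counts)]
        if vals.size and (np.any(vals < 0) | np.any(vals > 2) | np.any(vals != np.round(vals))):
            raise ValueError("allele counts must be 0, 1, 2 or missing")
        fr = self.snp_meta["freq"]
        bad = fr.notna() & ((fr <= 0) | (fr >= 1))
        if bad.any():
            raise ValueError(
                f"effect-allele frequencies outside (0,1) for {ids[bad].tolist()}"
            )

    @property
    def n_subjects(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.counts.shape[1]

    @property
    def snp_ids(self) -> list:
        return self.snp_meta["snp_id"].tolist()

    def observed_freqs(self) -> np.ndarray:
        """Empirical effect-allele frequency per SNP over non-missing calls."""
        return np.nanmean(self.counts, axis=0) / 2.0

    def select_snps(self, snp_ids) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.snp_meta["snp_id"])}
        missing = [s for s in snp_ids if s not in lookup]
        if missing:
            raise KeyError(f"SNPs not present: {missing}")
        ix = [lookup[s] for s in snp_ids]
        return GenotypeMatrix(
            subject_ids=self.subject_ids.copy(),
            snp_meta=self.snp_meta.iloc[ix].reset_index(drop=True),
            counts=self.counts[:, ix].copy(),
        )

    def select_subjects(self, subject_ids) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.subject_ids)}
        missing = [s for s in subject_ids if s not in lookup]
        if missing:
            raise KeyError(f"subjects not present: {missing[:5]}")
        ix = [lookup[s] for s in subject_ids]
        return GenotypeMatrix(
            subject_ids=self.subject_ids[ix],
            snp_meta=self.snp_meta.copy(),
            counts=self.counts[ix].copy(),
        )


def validate_phenotypes(phen: pd.DataFrame) -> pd.DataFrame:
    """Check the phenotype schema invariants; return the table unchanged.

    Raises :class:`PhenotypeValidationError` naming the first offending row.
    """
    missing_cols = [c for c in PHENOTYPE_COLUMNS if c not in phen.columns]
    if missing_cols:
        raise PhenotypeValidationError(f"missing columns: {missing_cols}")

    def _fail(mask, msg):
        if mask.any():
            row = int(np.flatnonzero(np.asarray(mask))[0])
            raise PhenotypeValidationError(f"row {row}: {msg}")

    if phen["subject_id"].duplicated().any():
        _fail(phen["subject_id"].duplicated(), "duplicate subject_id")
    _fail(~phen["status"].isin(["case", "control"]), "status must be case/control")
    _fail(~(phen["event_age"] > 0) | ~np.isfinite(phen["event_age"]),
          "event_age must be positive and finite")
    is_case = phen["status"] == "case"
    _fail(~is_case & phen["significant"].notna(),
          "significant defined for a control")
    _fail(~is_case & (phen["fatal"] == 1), "fatal flagged for a control")
    _fail((phen["fatal"] == 1) & (phen["significant"] != 1),
          "fatal case must be clinically significant")
    _fail((phen["fatal"] == 1) & phen["death_age"].isna(),
          "fatal case without death_age")
    _fail((phen["fatal"] != 1) & phen["death_age"].notna(),
          "death_age present for non-fatal subject")
    _fail(phen["death_age"].notna() & (phen["death_age"] < phen["event_age"]),
          "death_age earlier than event_age")
    _fail(~phen["family_history"].isin(["yes", "no", "unknown"]),
          "family_history must be yes/no/unknown")
    for col in ("significant", "fatal", "psa_positive", "biopsy_significant"):
        vals = phen[col].dropna()
        _fail(phen[col].notna() & ~phen[col].isin([0, 1]),
              f"{col} must be 0/1/NA")
    return phen


def validate_weights(weights: pd.DataFrame) -> pd.DataFrame:
    """Check a SNP weight table (snp_id, effect_allele, beta)."""
    for c in ("snp_id", "effect_allele", "beta"):
        if c not in weights.columns:
            raise ValueError(f"weight table missing column {c!r}")
    if weights["snp_id"].duplicated().any():
        dup = weights.loc[weights["snp_id"].duplicated(), "snp_id"].tolist()
        raise ValueError(f"duplicate snp_id in weight table: {dup}")
    if not np.all(np.isfinite(weights["beta"].to_numpy(dtype=float))):
        raise ValueError("non-finite beta in weight table")
    return weights


def empty_phenotypes(n: int) -> pd.DataFrame:
    """Phenotype frame skeleton with all optional fields missing."""
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:06d}" for i in range(n)],
            "status": ["control"] * n,
            "event_age": np.full(n, np.nan),
            "significant": np.full(n, np.nan),
            "fatal": np.zeros(n),
            "death_age": np.full(n, np.nan),
            "family_history": ["unknown"] * n,
            "psa_positive": np.full(n, np.nan),
            "biopsy_significant": np.full(n, np.nan),
            "pc1": np.zeros(n),
            "pc2": np.zeros(n),
            "pc3": np.zeros(n),
            "pc4": np.zeros(n),
        }
    )
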
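"""Synthetic cohort generator.

Emulates the statistical structure of a case-enriched genotype/phenotype
consortium dataset so the whole pipeline is testable without restricted
data: Hardy-Weinberg genotypes with configurable allele frequencies,
near-duplicate SNP pairs, a Weibull proportional-hazards age-at-onset model
with sparse per-allele log-hazard effects, censoring of controls at last
follow-up, case oversampling, a clinical-significance sub-phenotype derived
from drawn clinical records, prostate-cancer deaths in a subset of
significant cases, family history linked logistically to the true genetic
burden, and a PSA-screening layer with a fixed case:control ratio among
screen-positives.

All draws are keyed to ``SimulationConfig.seed`` through independent
per-stage streams, so any two runs with equal seed and config are
byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import GenotypeMatrix, validate_phenotypes

__all__ = [
    "SimulationConfig",
    "ClinicalRecord",
    "classify_significance",
    "simulate_genotypes",
    "simulate_onset",
    "apply_case_control_sampling",
    "simulate_screening",
    "simulate_cohort",
    "MissingDataError",
]


class MissingDataError(ValueError):
    """A clinical record field required for classification is absent."""


@dataclass
class ClinicalRecord:
    """Diagnostic work-up of one prostate cancer case."""

    gleason: Optional[int]       # Gleason score, 2-10
    psa: Optional[float]         # ng/mL at diagnosis
    t_stage: Optional[str]       # T1..T4
    node_positive: Optional[bool]
    metastatic: Optional[bool]

    def __post_init__(self):
        if self.gleason is not None and not (2 <= self.gleason <= 10):
            raise ValueError(f"gleason {self.gleason} outside [2, 10]")
        if self.psa is not None and self.psa < 0:
            raise ValueError("psa must be non-negative")
        if self.t_stage is not None and self.t_stage not in {"T1", "T2", "T3", "T4"}:
            raise ValueError(f"invalid t_stage {self.t_stage!r}")


def classify_significance(rec: ClinicalRecord) -> bool:
    """Clinically significant disease: Gleason >= 7, PSA >= 10 ng/mL,
    stage T3-T4, nodal or distant metastasis (any criterion suffices).

    A missing field raises :class:`MissingDataError`; no silent default.
    """
    for name in ("gleason", "psa", "t_stage", "node_positive", "metastatic"):
        if getattr(rec, name) is None:
            raise MissingDataError(f"clinical record field {name!r} is missing")
    return bool(
        rec.gleason >= 7
        or rec.psa >= 10.0
        or rec.t_stage in ("T3", "T4")
        or rec.node_positive
        or rec.metastatic
    )


@dataclass
class SimulationConfig:
    """Generator parameters; defaults emulate a case-enriched consortium
    cohort of a late-onset disease (see docs/methods.md for the rationale
    behind each default)."""

    n_subjects: int = 10_000
    n_snps: int = 100
    allele_freqs: Optional[np.ndarray] = None   # drawn U(0.05, 0.5) if None
    n_causal: int = 20
    causal_betas: Optional[np.ndarray] = None   # +-linspace(0.15, 0.45) if None
    ld_dup_pairs: int = 5
    copy_fidelity: float = 0.99                  # per-allele copy probability
    baseline_shape: float = 4.5                  # Weibull shape (rising hazard)
    baseline_scale: float = 116.0                # Weibull scale, years
    censor_age_lo: float = 55.0                  # control last-follow-up bounds
    censor_age_hi: float = 90.0
    target_prevalence: float = 0.12              # population lifetime risk
    sampled_case_control_ratio: float = 2.0      # cases per control after sampling
    p_significant_given_case: float = 0.36
    p_fatal_given_significant: float = 0.25
    fatal_survival_mean: float = 5.0             # years diagnosis -> death
    fh_intercept: float = -2.2                   # logistic link to true burden
    fh_slope: float = 0.5
    fh_missing_fraction: float = 0.25
    psa_threshold: float = 3.0                   # ng/mL positivity semantics
    screen_controls_per_case: float = 2.0        # 1:2 case:control among PSA+
    pc_background_snps: int = 200                # extra markers for the PC SVD
    seed: int = 0

    def __post_init__(self):
        if self.allele_freqs is not None:
            self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
            if self.allele_freqs.shape != (self.n_snps,):
                raise ValueError("allele_freqs must have length n_snps")
            if np.any(~np.isfinite(self.allele_freqs)) or np.any(
                (self.allele_freqs <= 0) | (self.allele_freqs >= 1)
            ):
                raise ValueError("allele frequencies must be finite, in (0,1)")
        if self.causal_betas is not None:
            self.causal_betas = np.asarray(self.causal_betas, dtype=float)
            if self.causal_betas.shape != (self.n_causal,):
                raise ValueError("causal_betas must have length n_causal")
            if np.any(~np.isfinite(self.causal_betas)):
                raise ValueError("causal_betas must be finite")
        if not 0 <= self.n_causal <= self.n_snps:
            raise ValueError("need 0 <= n_causal <= n_snps")
        if 2 * self.ld_dup_pairs > self.n_snps:
            raise ValueError("too many LD duplicate pairs for n_snps")
        if not 0.95 < self.copy_fidelity <= 1.0:
            raise ValueError("copy_fidelity must lie in (0.95, 1]")
        if not 0 < self.target_prevalence < 1:
            raise ValueError("target_prevalence must lie in (0,1)")
        if self.sampled_case_control_ratio <= 0:
            raise ValueError("sampled_case_control_ratio must be positive")
        for name in (
            "p_significant_given_case",
            "p_fatal_given_significant",
            "fh_missing_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0,1]")
        if self.baseline_shape <= 0 or self.baseline_scale <= 0:
            raise ValueError("Weibull baseline parameters must be positive")
        if not 0 < self.censor_age_lo < self.censor_age_hi:
            raise ValueError("censor age bounds must satisfy 0 < lo < hi")

    def rng(self, stage: int) -> np.random.Generator:
        """Independent, reproducible stream for a pipeline stage."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stage,))
        )

    def resolved_freqs(self) -> np.ndarray:
        if self.allele_freqs is not None:
            return self.allele_freqs
        return self.rng(10).uniform(0.05, 0.5, size=self.n_snps)

    def resolved_betas(self) -> np.ndarray:
        if self.causal_betas is not None:
            return self.causal_betas
        if self.n_causal == 0:
            return np.zeros(0)
        mags = np.linspace(0.15, 0.45, self.n_causal)
        signs = np.where(np.arange(self.n_causal) % 2 == 0, 1.0, -1.0)
        return mags * signs

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("allele_freqs", "causal_betas"):
            if d[k] is not None:
                d[k] = np.asarray(d[k]).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for k in ("allele_freqs", "causal_betas"):
            if d.get(k) is not None:
                d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


# stage keys for the per-stage random streams
_STAGE_GENO = 0
_STAGE_ONSET = 1
_STAGE_SAMPLING = 2
_STAGE_SCREEN = 3

_ALLELES = ("A", "G")  # effect allele, other allele for synthetic SNPs


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Hardy-Weinberg genotypes plus constructed near-duplicate SNP pairs.

    Counts are Binomial(2, freq) per SNP. The last ``ld_dup_pairs`` SNPs are
    companions of SNPs 0..ld_dup_pairs-1: each of the companion's two alleles
    copies the partner's corresponding allele with probability
    ``copy_fidelity`` and is otherwise redrawn Bernoulli(freq), so the pair's
    genotypic correlation is about ``copy_fidelity**2`` (r2 > 0.95 for the
    admissible fidelity range) and exactly 1 at fidelity 1.
    """
    rng = config.rng(_STAGE_GENO)
    n, p = config.n_subjects, config.n_snps
    freqs = config.resolved_freqs().copy()
    counts = rng.binomial(2, freqs, size=(n, p)).astype(float)

    k = config.ld_dup_pairs
    for j in range(k):
        partner = j
        companion = p - k + j
        f = freqs[partner]
        # per-allele copy: decompose the partner count into two alleles
        a1 = (counts[:, partner] >= 1).astype(float)
        a2 = (counts[:, partner] == 2).astype(float)
        keep1 = rng.random(n) < config.copy_fidelity
        keep2 = rng.random(n) < config.copy_fidelity
        new1 = np.where(keep1, a1, rng.binomial(1, f, size=n))
        new2 = np.where(keep2, a2, rng.binomial(1, f, size=n))
        counts[:, companion] = new1 + new2
        freqs[companion] = f

    meta = pd.DataFrame(
        {
            "snp_id": [f"snp{j:04d}" for j in range(p)],
            "chrom": ["1"] * p,
            "pos": np.arange(1, p + 1) * 1000,
            "effect_allele": [_ALLELES[0]] * p,
            "other_allele": [_ALLELES[1]] * p,
            "freq": freqs,
        }
    )
    subject_ids = np.array([f"S{i:06d}" for i in range(n)], dtype=object)
    return GenotypeMatrix(subject_ids=subject_ids, snp_meta=meta, counts=counts)


def true_linear_predictor(genotypes: GenotypeMatrix, config: SimulationConfig):
    """Centered true genetic burden sum(beta_i * x_i) of each subject."""
    betas = config.resolved_betas()
    if config.n_causal == 0:
        return np.zeros(genotypes.n_subjects)
    if genotypes.n_snps < config.n_causal:
        raise ValueError("genotype matrix has fewer SNPs than n_causal")
    lp = genotypes.counts[:, : config.n_causal] @ betas
    return lp - lp.mean()


def _draw_clinical_record(rng: np.random.Generator, significant: bool) -> ClinicalRecord:
    """Random diagnostic record consistent with the target significance."""
    if not significant:
        return ClinicalRecord(
            gleason=int(rng.integers(5, 7)),          # 5 or 6
            psa=float(rng.uniform(0.5, 9.9)),
            t_stage="T1" if rng.random() < 0.6 else "T2",
            node_positive=False,
            metastatic=False,
        )
    # pick which criteria fire (at least one)
    which = rng.random(5)
    fire = which < np.array([0.6, 0.4, 0.3, 0.1, 0.05])
    if not fire.any():
        fire[0] = True
    return ClinicalRecord(
        gleason=int(rng.integers(7, 11)) if fire[0] else int(rng.integers(5, 7)),
        psa=float(rng.uniform(10.0, 60.0)) if fire[1] else float(rng.uniform(0.5, 9.9)),
        t_stage=("T3" if rng.random() < 0.7 else "T4") if fire[2]
        else ("T1" if rng.random() < 0.6 else "T2"),
        node_positive=bool(fire[3]),
        metastatic=bool(fire[4]),
    )


def simulate_onset(genotypes: GenotypeMatrix, config: SimulationConfig) -> pd.DataFrame:
    """Phenotypes from the Weibull proportional-hazards onset model.

    Latent onset age T satisfies S(t|x) = exp(-(t/scale)^shape * e^lp) with
    lp the centered true genetic burden; a subject is a case if T precedes
    the uniform last-follow-up age, else a control censored there. Clinical
    significance, fatal outcomes, family history and the first four genotype
    principal components are attached as described in docs/methods.md.
    """
    rng = config.rng(_STAGE_ONSET)
    n = genotypes.n_subjects
    lp = true_linear_predictor(genotypes, config)

    u = rng.uniform(size=n)
    onset = config.baseline_scale * (-np.log(u) / np.exp(lp)) ** (
        1.0 / config.baseline_shape
    )
    censor = rng.uniform(config.censor_age_lo, config.censor_age_hi, size=n)
    is_case = onset <= censor
    event_age = np.where(is_case, onset, censor)

    significant = np.full(n, np.nan)
    fatal = np.zeros(n)
    death_age = np.full(n, np.nan)
    case_idx = np.flatnonzero(is_case)
    sig_draw = rng.uniform(size=n)
    fatal_draw = rng.uniform(size=n)
    death_wait = rng.exponential(config.fatal_survival_mean, size=n)
    for i in case_idx:
        rec = _draw_clinical_record(rng, sig_draw[i] < config.p_significant_given_case)
        sig = classify_significance(rec)
        significant[i] = float(sig)
        if sig and fatal_draw[i] < config.p_fatal_given_significant:
            fatal[i] = 1.0
            death_age[i] = event_age[i] + death_wait[i]

    # family history: logistic in the true burden, missing completely at random
    p_fh = 1.0 / (1.0 + np.exp(-(config.fh_intercept + config.fh_slope * lp)))
    fh = np.where(rng.uniform(size=n) < p_fh, "yes", "no").astype(object)
    fh[rng.uniform(size=n) < config.fh_missing_fraction] = "unknown"

    # ancestry PCs: SVD of the candidate matrix augmented with background
    # markers, mirroring genome-wide PC computation (candidate SNPs are a
    # negligible fraction of the markers the axes are built from, so the
    # covariates are not collinear with the candidate columns)
    if config.pc_background_snps > 0:
        bg_freqs = rng.uniform(0.05, 0.5, size=config.pc_background_snps)
        bg = rng.binomial(2, bg_freqs, size=(n, config.pc_background_snps))
        pc_input = np.column_stack([genotypes.counts, bg.astype(float)])
    else:
        pc_input = genotypes.counts
    pcs = _principal_components(pc_input, 4)

    phen = pd.DataFrame(
        {
            "subject_id": genotypes.subject_ids,
            "status": np.where(is_case, "case", "control"),
            "event_age": event_age,
            "significant": significant,
            "fatal": fatal,
            "death_age": death_age,
            "family_history": fh,
            "psa_positive": np.full(n, np.nan),
            "biopsy_significant": np.full(n, np.nan),
            "pc1": pcs[:, 0],
            "pc2": pcs[:, 1],
            "pc3": pcs[:, 2],
            "pc4": pcs[:, 3],
        }
    )
    phen.attrs["population_prevalence"] = float(is_case.mean())
    return validate_phenotypes(phen)


def _principal_components(counts: np.ndarray, k: int) -> np.ndarray:
    """First k left singular vectors of the column-centered genotype matrix,
    scaled to unit variance (ancestry-covariate construction)."""
    X = counts - np.nanmean(counts, axis=0)
    X = np.nan_to_num(X)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    k = min(k, u.shape[1])
    pcs = u[:, :k]
    sd = pcs.std(axis=0)
    sd[sd == 0] = 1.0
    out = np.zeros((counts.shape[0], 4))
    out[:, :k] = pcs / sd
    return out


def apply_case_control_sampling(
    phen: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Subsample the population to the configured case:control ratio.

    Keeps every retainable case/control pair count maximal subject to
    ``ratio = cases per control``; the realized population prevalence is
    carried through ``phen.attrs['population_prevalence']`` so downstream
    sample weights remain computable. Deterministic given the config seed.
    """
    rng = config.rng(_STAGE_SAMPLING)
    r = config.sampled_case_control_ratio
    case_ix = np.flatnonzero((phen["status"] == "case").to_numpy())
    ctrl_ix = np.flatnonzero((phen["status"] == "control").to_numpy())
    n_ctrl = min(len(ctrl_ix), int(np.floor(len(case_ix) / r)))
    n_case = min(len(case_ix), int(round(r * n_ctrl)))
    if n_case == 0 or n_ctrl == 0:
        raise ValueError(
            f"ratio {r} unattainable from {len(case_ix)} cases / "
            f"{len(ctrl_ix)} controls"
        )
    keep = np.concatenate(
        [
            rng.choice(case_ix, size=n_case, replace=False),
            rng.choice(ctrl_ix, size=n_ctrl, replace=False),
        ]
    )
    keep.sort()
    out = phen.iloc[keep].reset_index(drop=True)
    out.attrs = dict(phen.attrs)
    return out


def simulate_screening(phen: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """PSA-screening layer: every case is screen-positive, and screen-positive
    controls are drawn to hold the configured case:control ratio among
    PSA-positives. Biopsy outcome equals clinical significance for cases and
    is negative for screen-positive controls."""
    rng = config.rng(_STAGE_SCREEN)
    out = phen.copy()
    out.attrs = dict(phen.attrs)
    is_case = (out["status"] == "case").to_numpy()
    n_case = int(is_case.sum())
    ctrl_ix = np.flatnonzero(~is_case)
    n_pos_ctrl = int(round(config.screen_controls_per_case * n_case))
    if n_pos_ctrl > len(ctrl_ix):
        raise ValueError(
            f"cannot mark {n_pos_ctrl} screen-positive controls: only "
            f"{len(ctrl_ix)} controls available"
        )
    pos_ctrl = rng.choice(ctrl_ix, size=n_pos_ctrl, replace=False)
    psa_positive = np.zeros(len(out))
    psa_positive[is_case] = 1.0
    psa_positive[pos_ctrl] = 1.0
    biopsy = np.full(len(out), np.nan)
    biopsy[is_case] = out.loc[is_case, "significant"].to_numpy()
    biopsy[pos_ctrl] = 0.0
    out["psa_positive"] = psa_positive
    out["biopsy_significant"] = biopsy
    return validate_phenotypes(out)


def simulate_cohort(config: SimulationConfig):
    """Genotypes plus population phenotypes in one call."""
    g = simulate_genotypes(config)
    phen = simulate_onset(g, config)
    return g, phen
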
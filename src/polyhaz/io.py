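"""Reading and writing the pipeline's file formats.

Genotypes travel as VCF 4.2 (allele counts = number of ALT alleles, missing
call = missing entry) or as a dosage TSV; phenotypes and SNP weights as TSV
with header, missing coded "NA"; simulation configs as YAML. All writers are
deterministic: identical inputs produce byte-identical files (the VCF header
carries no date line), and all numeric text uses the C locale with "." as
the decimal point.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    PHENOTYPE_COLUMNS,
    GenotypeMatrix,
    validate_phenotypes,
    validate_weights,
)
from .simulate import SimulationConfig

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_weights",
    "write_weights",
    "read_config",
    "write_config",
]

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">\n'
)


def _fmt_float(x: float) -> str:
    """Full-precision, locale-independent float text (round-trips exactly)."""
    if isinstance(x, float) and math.isnan(x):
        return "NA"
    return repr(float(x))


def read_genotypes(path, fmt: str = "vcf") -> GenotypeMatrix:
    """Load a genotype matrix from ``vcf`` or ``dosage-tsv``.

    VCF: allele count is the number of ALT alleles in GT; ``./.`` becomes a
    missing entry; only biallelic records are accepted. Dosage TSV: first
    column ``subject_id``, remaining columns are literal per-SNP counts.
    """
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "dosage-tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    meta = {k: [] for k in ("snp_id", "chrom", "pos", "effect_allele",
                            "other_allele", "freq")}
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multi-allelic record {var.CHROM}:{var.POS} ({var.ID}) "
                "is not supported"
            )
        # gt_types: 0 hom-ref, 1 het, 3 hom-alt, 2 unknown/missing
        gt = var.gt_types
        counts = np.choose(gt, [0.0, 1.0, np.nan, 2.0])
        rows.append(counts)
        meta["snp_id"].append(var.ID if var.ID not in (None, ".") else
                              f"{var.CHROM}:{var.POS}")
        meta["chrom"].append(str(var.CHROM))
        meta["pos"].append(int(var.POS))
        meta["effect_allele"].append(var.ALT[0])
        meta["other_allele"].append(var.REF)
        af = var.INFO.get("AF")
        meta["freq"].append(float(af) if af is not None else np.nan)
    vcf.close()
    counts = (
        np.column_stack(rows) if rows else np.empty((len(samples), 0))
    )
    return GenotypeMatrix(
        subject_ids=np.array(samples, dtype=object),
        snp_meta=pd.DataFrame(meta),
        counts=counts,
    )


def _read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"subject_id": str})
    if df.columns[0] != "subject_id":
        raise ValueError("dosage TSV must start with a subject_id column")
    snp_ids = list(df.columns[1:])
    counts = df[snp_ids].to_numpy(dtype=float)
    meta = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": ["."] * len(snp_ids),
            "pos": np.arange(1, len(snp_ids) + 1),
            "effect_allele": ["ALT"] * len(snp_ids),
            "other_allele": ["REF"] * len(snp_ids),
            "freq": [np.nan] * len(snp_ids),
        }
    )
    return GenotypeMatrix(
        subject_ids=df["subject_id"].to_numpy(dtype=object),
        snp_meta=meta,
        counts=counts,
    )


_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_genotypes(g: GenotypeMatrix, path, fmt: str = "vcf") -> None:
    """Inverse of :func:`read_genotypes` (VCF 4.2 or dosage TSV)."""
    if fmt == "vcf":
        _write_vcf(g, path)
    elif fmt == "dosage-tsv":
        _write_dosage_tsv(g, path)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")


def _write_vcf(g: GenotypeMatrix, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(_VCF_HEADER)
        for chrom in dict.fromkeys(g.snp_meta["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        cols = "\t".join(str(s) for s in g.subject_ids)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        for j in range(g.n_snps):
            m = g.snp_meta.iloc[j]
            info = "." if pd.isna(m["freq"]) else f"AF={_fmt_float(m['freq'])}"
            gts = "\t".join(
                "./." if np.isnan(c) else _GT_CODE[c] for c in g.counts[:, j]
            )
            fh.write(
                f"{m['chrom']}\t{int(m['pos'])}\t{m['snp_id']}\t"
                f"{m['other_allele']}\t{m['effect_allele']}\t.\t.\t{info}\tGT\t{gts}\n"
            )


def _write_dosage_tsv(g: GenotypeMatrix, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("subject_id\t" + "\t".join(g.snp_ids) + "\n")
        for i, sid in enumerate(g.subject_ids):
            vals = "\t".join(
                "NA" if np.isnan(c) else str(int(c)) for c in g.counts[i]
            )
            fh.write(f"{sid}\t{vals}\n")


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype TSV -> validated DataFrame (missing coded NA)."""
    df = pd.read_csv(
        path,
        sep="\t",
        na_values=["NA"],
        keep_default_na=False,
        dtype={"subject_id": str, "status": str, "family_history": str},
        float_precision="round_trip",
    )
    for col in ("event_age", "significant", "fatal", "death_age",
                "psa_positive", "biopsy_significant", "pc1", "pc2", "pc3", "pc4"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
    return validate_phenotypes(df)


def write_phenotypes(phen: pd.DataFrame, path) -> None:
    validate_phenotypes(phen)
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(PHENOTYPE_COLUMNS) + "\n")
        for _, row in phen[PHENOTYPE_COLUMNS].iterrows():
            cells = []
            for col in PHENOTYPE_COLUMNS:
                v = row[col]
                if col in ("subject_id", "status", "family_history"):
                    cells.append(str(v))
                elif col in ("significant", "fatal", "psa_positive",
                             "biopsy_significant"):
                    cells.append("NA" if pd.isna(v) else str(int(v)))
                else:
                    cells.append(_fmt_float(v) if not pd.isna(v) else "NA")
            fh.write("\t".join(cells) + "\n")


def read_weights(path) -> pd.DataFrame:
    """SNP weight TSV (snp_id, effect_allele, beta) -> validated DataFrame."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "effect_allele": str},
                     float_precision="round_trip")
    df["beta"] = pd.to_numeric(df["beta"], errors="raise")
    return validate_weights(df)


def write_weights(weights: pd.DataFrame, path) -> None:
    validate_weights(weights)
    with open(path, "w", newline="\n") as fh:
        fh.write("snp_id\teffect_allele\tbeta\n")
        for _, row in weights.iterrows():
            fh.write(
                f"{row['snp_id']}\t{row['effect_allele']}\t{_fmt_float(row['beta'])}\n"
            )


def read_config(path) -> SimulationConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ValueError("config YAML must be a mapping")
    unknown = set(d) - set(SimulationConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    return SimulationConfig.from_dict(d)


def write_config(config: SimulationConfig, path) -> None:
    with open(path, "w", newline="\n") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
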
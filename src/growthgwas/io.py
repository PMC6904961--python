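"""File formats: phenotype TSV, genotype VCF / dosage TSV, summary-stats TSV.

All tables are plain tab-separated text.  Summary-statistics files carry
``# key=value`` provenance header lines (stage, study, trait, lambda, seed,
...) above the column header, and floats are serialized with 12 significant
digits so read(write(x)) round-trips numerically.  METAL-style column
aliases (MarkerName, Effect, StdErr, P-value, ...) are accepted on read.
Genomic coordinates are 1-based throughout (VCF convention); dosages count
the effect allele (ALT) and lie in [0, 2].
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import GenotypeMatrix, SnpSpec

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.12g"

PHENO_COLUMNS = ["study", "id", "sex", "ga_weeks", "age_years", "weight_kg", "height_cm"]

SUMSTAT_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P",
                   "N", "INFO", "HWE_P"]
_SUMSTAT_TO_INTERNAL = {
    "SNP": "snp_id", "CHR": "chrom", "POS": "pos", "EA": "ea", "OA": "oa",
    "EAF": "eaf", "BETA": "beta", "SE": "se", "P": "p", "N": "n",
    "INFO": "info", "HWE_P": "hwe_p",
}
_METAL_ALIASES = {
    "MarkerName": "SNP", "Marker": "SNP", "Chromosome": "CHR", "Position": "POS",
    "Allele1": "EA", "Allele2": "OA", "Freq1": "EAF", "Effect": "BETA",
    "StdErr": "SE", "P-value": "P", "Pvalue": "P", "Weight": "N",
}


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def write_phenotypes(measurements: pd.DataFrame, path) -> None:
    """Write a long phenotype table (one row per measurement)."""
    df = measurements[PHENO_COLUMNS]
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype TSV; malformed rows are dropped and logged with
    their line numbers.  A missing required column is an error naming it."""
    df = pd.read_csv(path, sep="\t", dtype={"study": str, "id": str})
    for col in PHENO_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"phenotype file {path} is missing column {col!r}")
    numeric = ["sex", "ga_weeks", "age_years", "weight_kg", "height_cm"]
    for col in numeric:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = (
        df[numeric].isna().any(axis=1)
        | ~df["sex"].isin([0, 1])
        | (df["age_years"] < 0) | (df["age_years"] > 13)
        | (df["weight_kg"] <= 0) | (df["height_cm"] <= 0)
    )
    for idx in df.index[bad]:
        # +2: header line and 1-based numbering
        logger.warning("%s line %d: malformed row dropped", path, idx + 2)
    out = df[~bad].reset_index(drop=True)
    out["sex"] = out["sex"].astype(int)
    out["ga_weeks"] = out["ga_weeks"].astype(int)
    return out


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def write_summary_stats(records: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """Write a summary-statistics table with ``# key=value`` provenance lines."""
    df = records.rename(columns={v: k for k, v in _SUMSTAT_TO_INTERNAL.items()})
    cols = [c for c in SUMSTAT_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols and c in ("study", "stage", "reason", "tier")]
    with open(path, "w") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}={value}\n")
        df[cols].to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def read_summary_stats(path) -> tuple[pd.DataFrame, dict]:
    """Read a summary-statistics TSV (canonical or METAL column names).

    Returns the table with internal column names and the provenance dict
    parsed from leading ``# key=value`` lines.
    """
    provenance: dict[str, str] = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                provenance[key.strip()] = value.strip()
    df = pd.read_csv(path, sep="\t", skiprows=skip)
    df = df.rename(columns=_METAL_ALIASES).rename(columns=_SUMSTAT_TO_INTERNAL)
    return df, provenance


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write genotypes as VCF v4.2 with DS (and GT for hard calls)."""
    ids = list(genotypes.dosages.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        seen: list[str] = []
        for snp in genotypes.panel:
            if snp.chrom not in seen:
                seen.append(snp.chrom)
                fh.write(f"##contig=<ID={snp.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description='
                 '"Estimated alternate allele dosage">\n')
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,Description='
                 '"Imputation info score">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in ids) + "\n")
        for snp in genotypes.panel:
            dose = genotypes.dosages[snp.snp_id].to_numpy()
            info = genotypes.info.get(snp.snp_id, 1.0)
            hard = np.allclose(np.round(dose), dose)
            fields = []
            for d in dose:
                ds = FLOAT_FMT % d
                if hard:
                    g = int(round(d))
                    gt = ["0/0", "0/1", "1/1"][g]
                    fields.append(f"{gt}:{ds}")
                else:
                    fields.append(ds)
            fmt = "GT:DS" if hard else "DS"
            # effect allele stored as ALT so that DS counts it
            fh.write(
                f"{snp.chrom}\t{snp.pos}\t{snp.snp_id}\t{snp.other_allele}\t"
                f"{snp.effect_allele}\t.\tPASS\tINFO={info:g}\t{fmt}\t"
                + "\t".join(fields) + "\n"
            )


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    panel: list[SnpSpec] = []
    columns: dict[str, np.ndarray] = {}
    info_scores: dict[str, float] = {}
    for variant in vcf:
        if len(variant.ALT) != 1:
            logger.warning("skipping multi-allelic site %s:%s", variant.CHROM, variant.POS)
            continue
        snp_id = variant.ID or f"{variant.CHROM}:{variant.POS}"
        ds = None
        try:
            arr = variant.format("DS")
            if arr is not None:
                ds = np.asarray(arr, dtype=float).reshape(-1)
        except KeyError:
            ds = None
        if ds is None:
            gts = np.asarray(variant.genotype.array())[:, :2]
            ds = np.where((gts >= 0).all(axis=1), gts.clip(0).sum(axis=1), np.nan)
        ds = np.clip(ds.astype(float), 0.0, 2.0)
        info = variant.INFO.get("INFO")
        info_scores[snp_id] = float(info) if info is not None else 1.0
        panel.append(SnpSpec(
            snp_id=snp_id, chrom=str(variant.CHROM), pos=int(variant.POS),
            effect_allele=variant.ALT[0], other_allele=variant.REF,
            maf=float(min(np.nanmean(ds) / 2.0, 1 - np.nanmean(ds) / 2.0)),
        ))
        columns[snp_id] = ds
    df = pd.DataFrame(columns, index=pd.Index(ids, name="id"))
    return GenotypeMatrix(dosages=df, panel=tuple(panel),
                          info=pd.Series(info_scores, name="info"))


def write_dosage_tsv(genotypes: GenotypeMatrix, path) -> None:
    """Write genotypes as a wide dosage TSV (one row per SNP)."""
    meta = pd.DataFrame(
        {
            "SNP": [s.snp_id for s in genotypes.panel],
            "CHR": [s.chrom for s in genotypes.panel],
            "POS": [s.pos for s in genotypes.panel],
            "EA": [s.effect_allele for s in genotypes.panel],
            "OA": [s.other_allele for s in genotypes.panel],
            "INFO": [genotypes.info.get(s.snp_id, 1.0) for s in genotypes.panel],
        }
    )
    wide = genotypes.dosages.T.reset_index(drop=True)
    pd.concat([meta, wide], axis=1).to_csv(path, sep="\t", index=False,
                                           float_format=FLOAT_FMT)


def _read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["SNP", "CHR", "POS", "EA", "OA", "INFO"]
    for col in meta_cols:
        if col not in df.columns:
            raise ValueError(f"dosage file {path} is missing column {col!r}")
    sample_cols = [c for c in df.columns if c not in meta_cols]
    panel = tuple(
        SnpSpec(snp_id=str(r.SNP), chrom=str(r.CHR), pos=int(r.POS),
                effect_allele=str(r.EA), other_allele=str(r.OA),
                maf=float(min(m / 2.0, 1 - m / 2.0)))
        for r, m in zip(df.itertuples(), df[sample_cols].mean(axis=1))
    )
    dosages = pd.DataFrame(
        df[sample_cols].to_numpy(dtype=float).T,
        index=pd.Index(sample_cols, name="id"),
        columns=df["SNP"].astype(str),
    )
    info = pd.Series(df["INFO"].to_numpy(dtype=float),
                     index=df["SNP"].astype(str), name="info")
    return GenotypeMatrix(dosages=dosages, panel=panel, info=info)


def read_genotypes(path, format: str = "vcf") -> GenotypeMatrix:
    """Read genotypes from VCF v4.2 (GT or DS; DS preferred) or a dosage TSV."""
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage_tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}; use 'vcf' or 'dosage_tsv'")


# ---------------------------------------------------------------------------
# ground truth sidecar
# ---------------------------------------------------------------------------

def write_truth_json(path, config, studies) -> None:
    """Write the simulation ground truth (per-study realized effects and
    latent trait summaries) next to the generated data."""
    payload = {
        "seed": config.seed,
        "n_individuals": config.n_individuals,
        "n_studies": config.n_studies,
        "between_study_sd": config.between_study_sd,
        "causal_effects": {
            snp: {"trait": eff.trait, "beta": eff.beta}
            for snp, eff in config.causal_effects.items()
        },
        "studies": {
            s.study_id: {
                "realized_effects": s.study_effects,
                "latent_trait_means": {
                    t: float(s.truth[t].mean()) for t in s.truth.columns
                },
            }
            for s in studies
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))
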
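"""Trait preparation, per-SNP association, QC filtering, genomic control.

Each derived trait is natural-log transformed (except the two age traits)
and converted to a z-score within study before association testing.  The
association model is ordinary least squares of the trait z-score on the
allele dosage, assuming an additive genetic effect and adjusting for sex
plus gestational age (sex only for the two rebound traits).  Betas are
therefore in SD units of the trait per effect allele.

Genomic control rescales standard errors by sqrt(lambda), where lambda is
the median association chi-square divided by the chi-square(1 df) median
(0.4549...); statistics are never shrunk when lambda <= 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .traits import covariate_set, transform_of

logger = logging.getLogger(__name__)

#: median of the chi-square distribution with 1 df
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))

SUMSTAT_FIELDS = ("snp_id", "chrom", "pos", "ea", "oa", "eaf", "beta", "se",
                  "p", "n", "info", "hwe_p", "study", "stage")


@dataclass
class TraitVector:
    """A trait ready for association: z-scored, with its analysis rules."""

    trait: str
    values: pd.Series            # index subject id; NaN = missing
    transform: str               # "log" or "none"
    covariates: str              # "sex+ga" or "sex"


@dataclass
class SummaryStatRecord:
    """Per-SNP association estimate in one study and stage."""

    snp_id: str
    chrom: str = ""
    pos: int = 0
    ea: str = ""
    oa: str = ""
    eaf: float = np.nan
    beta: float = np.nan
    se: float = np.nan
    p: float = np.nan
    n: int = 0
    info: float = 1.0
    hwe_p: float = np.nan
    study: str = ""
    stage: int = 1
    note: str = ""


@dataclass
class QCThresholds:
    """Pre-meta-analysis SNP filters.

    ``min_info`` applies under the IMPUTE dialect ("proper_info" score),
    ``min_r2`` under the MACH dialect.
    """

    min_maf: float = 0.01
    min_info: float = 0.4
    min_r2: float = 0.3
    min_hwe_p: float = 1e-4
    min_call_rate: float = 0.95

    def __post_init__(self) -> None:
        for name in ("min_maf", "min_info", "min_r2", "min_hwe_p", "min_call_rate"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


def prepare_trait(values: pd.Series, trait_name: str) -> TraitVector:
    """Log-transform (unless an age trait) and z-score a derived trait.

    Missing values are propagated.  Zero variance is an error, as is a
    non-positive value under the log transform (reported with subject ids).
    """
    transform = transform_of(trait_name)
    v = pd.Series(values, dtype=float).copy()
    obs = v.dropna()
    if obs.nunique() < 2:
        raise ValueError(f"trait {trait_name!r} has fewer than 2 distinct values")
    if transform == "log":
        bad = obs.index[obs <= 0]
        if len(bad):
            raise ValueError(
                f"trait {trait_name!r} has non-positive values under log transform "
                f"for subjects {list(bad[:5])}"
            )
        v = np.log(v)
    sd = v.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError(f"trait {trait_name!r} has zero variance")
    z = (v - v.mean()) / sd
    return TraitVector(trait=trait_name, values=z, transform=transform,
                       covariates=covariate_set(trait_name))


def _covariate_matrix(trait: TraitVector, covariates: pd.DataFrame,
                      extra: list[str] | None) -> pd.DataFrame:
    cols = ["sex"]
    if trait.covariates == "sex+ga":
        cols.append("ga_weeks")
    cols += list(extra or [])
    missing = [c for c in cols if c not in covariates.columns]
    if missing:
        raise ValueError(f"covariate table is missing columns {missing}")
    return covariates[cols]


def run_snp_association(
    trait: TraitVector,
    dosage: pd.Series,
    covariates: pd.DataFrame,
    snp: object | None = None,
    study: str = "",
    stage: int = 1,
    extra_covariates: list[str] | None = None,
) -> SummaryStatRecord:
    """OLS of a trait z-score on allele dosage with the trait's covariates.

    The two-sided P value uses the t distribution with the exact residual
    degrees of freedom.  A monomorphic SNP yields a flagged record with no
    estimate.  ``snp`` may carry snp_id/chrom/pos/allele metadata.
    """
    C = _covariate_matrix(trait, covariates, extra_covariates)
    df = pd.concat([trait.values.rename("y"), dosage.rename("dose"), C],
                   axis=1, join="inner").dropna()
    n = len(df)
    p_cov = C.shape[1]
    if n < p_cov + 2:
        raise ValueError(f"only {n} complete cases; need at least {p_cov + 2}")

    meta = {}
    if snp is not None:
        meta = dict(snp_id=snp.snp_id, chrom=str(snp.chrom), pos=int(snp.pos),
                    ea=snp.effect_allele, oa=snp.other_allele)
    dose = df["dose"].to_numpy()
    rec = SummaryStatRecord(
        snp_id=meta.get("snp_id", getattr(dosage, "name", "") or ""),
        chrom=meta.get("chrom", ""), pos=meta.get("pos", 0),
        ea=meta.get("ea", ""), oa=meta.get("oa", ""),
        eaf=float(dose.mean() / 2.0), n=n, study=study, stage=stage,
    )
    if np.ptp(dose) == 0:
        rec.note = "monomorphic"
        return rec
    if np.allclose(np.round(dose), dose):
        from .synthetic import hwe_chisq_p
        rec.hwe_p = hwe_chisq_p(dose)

    X = np.column_stack([np.ones(n), dose, df[C.columns].to_numpy(dtype=float)])
    y = df["y"].to_numpy()
    XtX_inv = np.linalg.pinv(X.T @ X)
    beta_hat = XtX_inv @ (X.T @ y)
    resid = y - X @ beta_hat
    dof = n - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    se = float(np.sqrt(sigma2 * XtX_inv[1, 1]))
    beta = float(beta_hat[1])
    rec.beta = beta
    rec.se = se
    rec.p = float(2.0 * stats.t.sf(abs(beta) / se, dof)) if se > 0 else 0.0
    return rec


def association_scan(
    trait: TraitVector,
    dosages: pd.DataFrame,
    covariates: pd.DataFrame,
    study: str = "",
    stage: int = 1,
    chunk_size: int = 4000,
) -> pd.DataFrame:
    """Vectorized per-SNP OLS scan over the columns of ``dosages``.

    Equivalent to calling :func:`run_snp_association` per SNP (complete
    cases on the trait and covariates; SNP dosages are assumed complete).
    Returns a summary-statistics frame with one row per SNP.
    """
    C = _covariate_matrix(trait, covariates, None)
    base = pd.concat([trait.values.rename("y"), C], axis=1, join="inner").dropna()
    base = base.loc[base.index.intersection(dosages.index)]
    ids = base.index
    n = len(ids)
    W = np.column_stack([np.ones(n), base[C.columns].to_numpy(dtype=float)])
    y = base["y"].to_numpy()
    # residualize trait and dosages on covariates (Frisch-Waugh)
    Q, _ = np.linalg.qr(W)
    y_r = y - Q @ (Q.T @ y)
    dof = n - W.shape[1] - 1
    yy = float(y_r @ y_r)

    out = {"snp_id": [], "eaf": [], "beta": [], "se": [], "p": [], "n": []}
    cols = list(dosages.columns)
    for start in range(0, len(cols), chunk_size):
        block = cols[start:start + chunk_size]
        D = dosages.loc[ids, block].to_numpy(dtype=float)
        D_r = D - Q @ (Q.T @ D)
        sxx = (D_r * D_r).sum(axis=0)
        sxy = D_r.T @ y_r
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = sxy / sxx
            rss = yy - beta * sxy
            se = np.sqrt(np.maximum(rss, 0.0) / dof / sxx)
            tval = np.abs(beta / se)
        p = 2.0 * stats.t.sf(tval, dof)
        mono = sxx <= 0
        beta[mono] = np.nan
        se[mono] = np.nan
        p[mono] = np.nan
        out["snp_id"] += block
        out["eaf"].append(D.mean(axis=0) / 2.0)
        out["beta"].append(beta)
        out["se"].append(se)
        out["p"].append(p)
        out["n"].append(np.full(len(block), n))
    df = pd.DataFrame({
        "snp_id": out["snp_id"],
        "eaf": np.concatenate(out["eaf"]),
        "beta": np.concatenate(out["beta"]),
        "se": np.concatenate(out["se"]),
        "p": np.concatenate(out["p"]),
        "n": np.concatenate(out["n"]).astype(int),
    })
    df["study"] = study
    df["stage"] = stage
    df["info"] = 1.0
    df["hwe_p"] = np.nan
    return df


def qc_filter(
    records: pd.DataFrame,
    thresholds: QCThresholds | None = None,
    dialect: str = "impute",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop SNPs failing MAF, imputation-quality, HWE or call-rate filters.

    A record survives iff it passes every applicable threshold; criteria
    whose field is absent or NaN are not applied.  Returns the surviving
    records and per-criterion exclusion counts.
    """
    if thresholds is None:
        thresholds = QCThresholds()
    if dialect not in ("impute", "mach"):
        raise ValueError(f"unknown imputation dialect {dialect!r}; use 'impute' or 'mach'")
    df = records.copy()
    n0 = len(df)
    counts: dict[str, int] = {}

    def apply(name: str, mask_fail: pd.Series) -> None:
        nonlocal df
        mask_fail = mask_fail.fillna(False)
        counts[name] = int(mask_fail.sum())
        df = df[~mask_fail]

    if "eaf" in df.columns:
        maf = np.minimum(df["eaf"], 1.0 - df["eaf"])
        apply("maf", maf < thresholds.min_maf)
    if "info" in df.columns:
        cutoff = thresholds.min_info if dialect == "impute" else thresholds.min_r2
        apply("info", df["info"] < cutoff)
    if "hwe_p" in df.columns:
        apply("hwe", df["hwe_p"] < thresholds.min_hwe_p)
    if "call_rate" in df.columns:
        apply("call_rate", df["call_rate"] < thresholds.min_call_rate)
    logger.info("QC: %d of %d records pass (%s)", len(df), n0,
                ", ".join(f"{k}:{v}" for k, v in counts.items()))
    return df, counts


def genomic_control(records: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Apply genomic control to a summary-statistics frame.

    lambda = median((beta/se)^2) / median of chi-square(1).  When lambda
    exceeds 1, standard errors are multiplied by sqrt(lambda) and P values
    recomputed from the corrected chi-square; otherwise records are
    unchanged.  Returns the (possibly adjusted) records and lambda.
    """
    ok = records["se"].notna() & (records["se"] > 0) & records["beta"].notna()
    chi2 = (records.loc[ok, "beta"] / records.loc[ok, "se"]) ** 2
    if len(chi2) == 0:
        raise ValueError("no usable records for genomic control")
    if len(chi2) < 100:
        warnings.warn(
            f"genomic control on only {len(chi2)} records; lambda is unstable",
            stacklevel=2,
        )
    lam = float(np.median(chi2) / CHI2_1_MEDIAN)
    out = records.copy()
    if lam > 1.0:
        out.loc[ok, "se"] = out.loc[ok, "se"] * np.sqrt(lam)
        chi_corr = (out.loc[ok, "beta"] / out.loc[ok, "se"]) ** 2
        out.loc[ok, "p"] = stats.chi2.sf(chi_corr, 1)
    return out, lam
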
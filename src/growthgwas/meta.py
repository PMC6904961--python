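"""Inverse-variance meta-analysis, double genomic control, SNP selection,
significance tiers and Efron's local false discovery rate.

The fixed-effects combined estimate weights each study by its inverse
squared standard error:

    beta = sum(b_i / se_i^2) / sum(1 / se_i^2),   se = (sum 1/se_i^2)^(-1/2)

Cochran's Q = sum(((b_i - beta)/se_i)^2) on k-1 df measures between-study
heterogeneity and I^2 = max(0, (Q - (k-1))/Q) * 100 the proportion of
variance it explains.  A DerSimonian-Laird random-effects combination is
available as an option; fixed effects is the default.

"Double" genomic control corrects the chi-square inflation factor lambda
once within each study and once more on the meta-analysed statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
import statsmodels.api as sm

from .assoc import genomic_control

logger = logging.getLogger(__name__)


@dataclass
class MetaRecord:
    """A combined per-SNP estimate with heterogeneity metadata."""

    snp_id: str
    beta: float
    se: float
    p: float
    k: int
    q: float
    q_p: float
    i2: float                   # percent
    stage: str = "stage1"       # stage1 / stage2 / combined
    lambda_meta: float = np.nan


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds for follow-up selection and combined significance tiers."""

    p_strict: float = 1e-7
    p_candidate: float = 1e-5
    candidate_snps: frozenset = frozenset()
    override_snps: frozenset = frozenset()
    genome_wide: float = 5e-8
    suggestive: float = 5e-6

    def __post_init__(self) -> None:
        if not self.p_strict < self.p_candidate:
            raise ValueError("p_strict must be smaller than p_candidate")


def ivw_meta(
    betas, ses, snp_id: str = "", stage: str = "stage1", method: str = "fixed",
) -> MetaRecord:
    """Inverse-variance-weighted combination of per-study estimates.

    ``method="fixed"`` (default) is the precision-weighted fixed-effects
    model; ``method="random"`` applies the DerSimonian-Laird tau^2.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0:
        raise ValueError("ivw_meta needs at least one estimate")
    if b.shape != s.shape:
        raise ValueError("betas and ses must have equal length")
    if np.any(~np.isfinite(s)) or np.any(s <= 0):
        raise ValueError("all standard errors must be positive and finite")
    w = 1.0 / s**2
    beta_f = float((w * b).sum() / w.sum())
    k = b.size
    q = float((w * (b - beta_f) ** 2).sum()) if k > 1 else 0.0
    q_p = float(stats.chi2.sf(q, k - 1)) if k > 1 else float("nan")
    i2 = float(max(0.0, (q - (k - 1)) / q) * 100.0) if q > 0 else 0.0

    if method == "fixed":
        beta, se = beta_f, float(w.sum() ** -0.5)
    elif method == "random":
        denom = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (q - (k - 1)) / denom) if k > 1 and denom > 0 else 0.0
        w_r = 1.0 / (s**2 + tau2)
        beta = float((w_r * b).sum() / w_r.sum())
        se = float(w_r.sum() ** -0.5)
    else:
        raise ValueError(f"unknown method {method!r}; use 'fixed' or 'random'")
    p = float(2.0 * stats.norm.sf(abs(beta) / se))
    return MetaRecord(snp_id=snp_id, beta=beta, se=se, p=p, k=k,
                      q=q, q_p=q_p, i2=i2, stage=stage)


def meta_analyze(
    study_tables: list[pd.DataFrame], stage: str = "stage1", method: str = "fixed",
) -> pd.DataFrame:
    """IVW-combine per-study summary statistics SNP by SNP.

    Tables are aligned on ``snp_id``; a SNP is combined across the studies
    in which it has a finite estimate.  Effect-allele frequency is combined
    weighted by sample size and sample sizes are summed.
    """
    if not study_tables:
        raise ValueError("no study tables given")
    stacked = pd.concat(study_tables, ignore_index=True)
    stacked = stacked[stacked["beta"].notna() & (stacked["se"] > 0)]
    rows = []
    for snp_id, g in stacked.groupby("snp_id", sort=False):
        rec = ivw_meta(g["beta"], g["se"], snp_id=snp_id, stage=stage, method=method)
        n_tot = int(g["n"].sum()) if "n" in g else 0
        eaf = float((g["eaf"] * g["n"]).sum() / g["n"].sum()) \
            if {"eaf", "n"} <= set(g.columns) and g["n"].sum() > 0 else np.nan
        row = {
            "snp_id": snp_id, "beta": rec.beta, "se": rec.se, "p": rec.p,
            "k": rec.k, "q": rec.q, "q_p": rec.q_p, "i2": rec.i2,
            "n": n_tot, "eaf": eaf, "stage": stage,
        }
        for col in ("chrom", "pos", "ea", "oa"):
            if col in g.columns:
                row[col] = g[col].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def double_gc_meta(
    study_tables: list[pd.DataFrame], stage: str = "stage1",
) -> tuple[pd.DataFrame, float]:
    """Second layer of double genomic control: IVW meta then GC on the meta
    statistics.  Per-study tables are expected to be GC-adjusted already
    (see :func:`growthgwas.assoc.genomic_control`).  Returns the adjusted
    meta table and lambda_meta.
    """
    meta = meta_analyze(study_tables, stage=stage)
    meta, lam = genomic_control(meta)
    meta["lambda_meta"] = lam
    return meta, lam


def select_for_followup(stage1: pd.DataFrame, config: SelectionConfig) -> pd.DataFrame:
    """Select stage-1 SNPs for stage-2 follow-up.

    A SNP is selected iff P < p_strict, or P < p_candidate while flagged as
    in/near a known obesity/metabolic candidate gene, or listed on the
    override allowlist (prior-evidence loci followed up regardless of the P
    thresholds).  Returns the selected rows with a ``reason`` column.
    """
    if len(stage1) == 0:
        return stage1.assign(reason=pd.Series(dtype=str))
    reasons = []
    for _, row in stage1.iterrows():
        if row["p"] < config.p_strict:
            reasons.append("p_strict")
        elif row["p"] < config.p_candidate and row["snp_id"] in config.candidate_snps:
            reasons.append("candidate_gene")
        elif row["snp_id"] in config.override_snps:
            reasons.append("override")
        else:
            reasons.append("")
    out = stage1.copy()
    out["reason"] = reasons
    selected = out[out["reason"] != ""].copy()
    logger.info("selected %d of %d SNPs for follow-up", len(selected), len(out))
    return selected


def classify_significance(
    combined: pd.DataFrame, config: SelectionConfig | None = None,
) -> pd.Series:
    """Tier each combined-stage SNP: genome-wide (< 5e-8, strict), suggestive
    (< 5e-6) or none."""
    if config is None:
        config = SelectionConfig()
    p = combined["p"]
    tier = pd.Series("none", index=combined.index, dtype=object)
    tier[p < config.suggestive] = "suggestive"
    tier[p < config.genome_wide] = "genome-wide"
    tier.name = "tier"
    return tier


# ---------------------------------------------------------------------------
# Efron local false discovery rate
# ---------------------------------------------------------------------------

@dataclass
class LocalFdrResult:
    fdr: np.ndarray              # per input z-value, in [0, 1]
    pi0: float
    z: np.ndarray


def _spline_basis(x: np.ndarray, lo: float, hi: float, df: int) -> np.ndarray:
    """Cubic B-spline basis with ``df`` columns on [lo, hi]."""
    degree = 3
    n_interior = df - degree
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    return BSpline.design_matrix(
        np.clip(x, lo, hi), knots, degree, extrapolate=False
    ).toarray()


def local_fdr(
    z, bins: int = 120, spline_df: int = 7, central_window: float = 1.0,
) -> LocalFdrResult:
    """Two-groups local fdr with a theoretical N(0,1) null.

    fdr(z) = pi0 * f0(z) / f(z), where the marginal density f is estimated
    by Poisson regression of histogram counts on a cubic spline basis
    (Lindsey's method) and pi0 by central matching: a quadratic fit of
    log f - log f0 over |z| < ``central_window``, exponentiated at z = 0 and
    capped at 1.
    """
    z = np.asarray(z, dtype=float)
    if z.size < 1000:
        raise ValueError(f"need at least 1000 z-values for a stable fit, got {z.size}")
    zmax = float(max(np.abs(z).max() * 1.01, 4.0))
    edges = np.linspace(-zmax, zmax, bins + 1)
    counts, _ = np.histogram(z, bins=edges)
    mids = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]

    B = _spline_basis(mids, -zmax, zmax, spline_df)
    X = sm.add_constant(B)
    fit = sm.GLM(counts, X, family=sm.families.Poisson()).fit()

    def density(at: np.ndarray) -> np.ndarray:
        Xa = sm.add_constant(_spline_basis(at, -zmax, zmax, spline_df),
                             has_constant="add")
        mu = fit.predict(Xa)
        return np.maximum(mu, 1e-300) / (z.size * width)

    central = mids[np.abs(mids) < central_window]
    ratio = np.log(density(central)) - stats.norm.logpdf(central)
    coef = np.polynomial.polynomial.polyfit(central, ratio, 2)
    pi0 = float(min(1.0, np.exp(coef[0])))

    fdr = np.clip(pi0 * stats.norm.pdf(z) / density(z), 0.0, 1.0)
    return LocalFdrResult(fdr=fdr, pi0=pi0, z=z)


def z_from_p(p, beta=None) -> np.ndarray:
    """Convert two-sided P values to z-values, signed by ``beta`` if given."""
    p = np.asarray(p, dtype=float)
    z = stats.norm.isf(p / 2.0)
    if beta is not None:
        z = z * np.sign(np.asarray(beta, dtype=float))
    return z
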
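"""Formula-level downstream GWAS statistics.

* variance explained by a SNP: h^2 = beta^2 * 2 f (1 - f) on a unit-variance
  trait;
* winner's-curse bias reduction by conditional-likelihood maximization
  (the naive estimate given selection at a two-sided significance cutoff),
  with the usual compromise estimator (naive + MLE)/2;
* effective number of independent tests from the eigenvalues of the
  phenotype correlation matrix (Li-Ji), and the Bonferroni-corrected alpha;
* summary-statistic genetic risk score effect (gtx-style precision-weighted
  fit of local betas on external weights) with heterogeneity-driven
  downward elimination;
* conditional-independence rule for lead/proxy SNP pairs;
* chi-square power analysis with noncentrality n * 2f(1-f) * b^2 * r^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import logsumexp


# ---------------------------------------------------------------------------
# variance explained
# ---------------------------------------------------------------------------

def variance_explained(beta: float, f: float) -> float:
    """Fraction of a unit-variance trait explained by a SNP:
    h^2 = beta^2 * 2 f (1 - f), with f the effect-allele frequency."""
    if not 0.0 < f < 1.0:
        raise ValueError(f"allele frequency must be in (0, 1), got {f}")
    return float(beta**2 * 2.0 * f * (1.0 - f))


# ---------------------------------------------------------------------------
# winner's curse
# ---------------------------------------------------------------------------

@dataclass
class WinnersCurseEstimate:
    naive: float
    se: float
    alpha: float
    z_c: float
    mle: float                  # conditional-likelihood bias-reduced estimate
    compromise: float           # (naive + mle) / 2


def _conditional_loglik(beta: float, beta_hat: float, se: float, z_c: float) -> float:
    # log density of beta_hat given selection |beta_hat/se| > z_c
    num = stats.norm.logpdf((beta_hat - beta) / se)
    denom = logsumexp([
        stats.norm.logcdf(beta / se - z_c),
        stats.norm.logcdf(-beta / se - z_c),
    ])
    return float(num - denom)


def winners_curse_mle(beta: float, se: float, selection_alpha: float) -> WinnersCurseEstimate:
    """Bias-reduced effect estimate under significance-threshold selection.

    Maximizes the likelihood of the observed estimate conditional on having
    passed the two-sided selection threshold ``selection_alpha``.  Defined
    only for estimates that were actually selected (|beta/se| > z_c).
    """
    if se <= 0:
        raise ValueError("se must be positive")
    if not 0.0 < selection_alpha < 1.0:
        raise ValueError("selection_alpha must be in (0, 1)")
    z_c = float(stats.norm.isf(selection_alpha / 2.0))
    if abs(beta / se) <= z_c:
        raise ValueError(
            f"estimate z={beta / se:.3f} not selected at this cutoff (z_c={z_c:.3f})")
    lo = min(0.0, beta) - 5.0 * se
    hi = max(0.0, beta) + 5.0 * se
    res = optimize.minimize_scalar(
        lambda b: -_conditional_loglik(b, beta, se, z_c),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8},
    )
    mle = float(res.x)
    return WinnersCurseEstimate(
        naive=float(beta), se=float(se), alpha=float(selection_alpha),
        z_c=z_c, mle=mle, compromise=(float(beta) + mle) / 2.0,
    )


# ---------------------------------------------------------------------------
# effective number of tests (Li-Ji)
# ---------------------------------------------------------------------------

@dataclass
class EffectiveTestsResult:
    eigenvalues: np.ndarray
    m_eff: float
    alpha: float
    alpha_corrected: float


def effective_tests(corr_matrix, alpha: float = 5e-8) -> EffectiveTestsResult:
    """Li-Ji effective number of independent phenotypes.

    m_eff = sum over eigenvalues of [ I(lam >= 1) + (lam - floor(lam)) ];
    the Bonferroni-corrected threshold is alpha / m_eff.  The input must be
    a symmetric correlation matrix with unit diagonal.
    """
    R = np.asarray(corr_matrix, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    lam = np.linalg.eigvalsh(R)
    if lam.min() < -1e-6:
        raise ValueError("correlation matrix is not positive semi-definite")
    lam = np.clip(lam, 0.0, None)  # absorb numerical negatives
    # snap near-integer eigenvalues: floor() is discontinuous, so 6 - 1e-15
    # must count as 6, not as 5 + 0.999...
    near = np.abs(lam - np.round(lam)) < 1e-9
    lam[near] = np.round(lam[near])
    m_eff = float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))
    return EffectiveTestsResult(
        eigenvalues=np.sort(lam)[::-1], m_eff=m_eff,
        alpha=float(alpha), alpha_corrected=float(alpha) / m_eff,
    )


# ---------------------------------------------------------------------------
# summary-statistic genetic risk score
# ---------------------------------------------------------------------------

@dataclass
class GrsResult:
    alpha_hat: float            # effect of the weighted score on the trait
    se: float
    p: float
    q_het: float
    p_het: float
    k: int
    h2_grs: float               # alpha^2 * sum(w^2 * 2 f (1-f)), unit trait variance
    removed: list = field(default_factory=list)


def _grs_fit(w: np.ndarray, b: np.ndarray, s: np.ndarray) -> tuple[float, float, float, float]:
    w2se = (w**2) / s**2
    alpha = float((w * b / s**2).sum() / w2se.sum())
    se = float(w2se.sum() ** -0.5)
    q = float((((b - alpha * w) / s) ** 2).sum())
    p_het = float(stats.chi2.sf(q, len(b) - 1)) if len(b) > 1 else float("nan")
    return alpha, se, q, p_het


def grs_effect(weights, betas, ses, eafs=None, het_alpha: float = 0.05) -> GrsResult:
    """Effect of an externally weighted genetic risk score on a trait,
    estimated from per-SNP summary statistics.

    alpha_hat = sum(w b / se^2) / sum(w^2 / se^2).  If the per-SNP effects
    are heterogeneous around the fitted score line (Cochran's Q on k-1 df,
    P < ``het_alpha``), SNPs are eliminated downwards — largest |beta|
    first — until the model is no longer heterogeneous.
    """
    w = np.asarray(weights, dtype=float)
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if w.size == 0:
        raise ValueError("grs_effect needs at least one SNP")
    if not (w.shape == b.shape == s.shape):
        raise ValueError("weights, betas and ses must have equal length")
    if np.any(s <= 0):
        raise ValueError("all standard errors must be positive")
    f = np.asarray(eafs, dtype=float) if eafs is not None else None
    if f is not None and (f.shape != w.shape or np.any((f <= 0) | (f >= 1))):
        raise ValueError("eafs must match the SNP count and lie in (0, 1)")

    idx = np.arange(w.size)
    removed: list = []
    while True:
        alpha, se, q, p_het = _grs_fit(w[idx], b[idx], s[idx])
        if len(idx) <= 1 or not (p_het < het_alpha):
            break
        drop = idx[np.argmax(np.abs(b[idx]))]
        removed.append(int(drop))
        idx = idx[idx != drop]
        if idx.size == 0:
            raise ValueError("all SNPs eliminated by the heterogeneity rule")

    h2 = float("nan")
    if f is not None:
        h2 = float(alpha**2 * np.sum(w[idx] ** 2 * 2.0 * f[idx] * (1.0 - f[idx])))
    p = float(2.0 * stats.norm.sf(abs(alpha) / se))
    return GrsResult(alpha_hat=alpha, se=se, p=p, q_het=q, p_het=p_het,
                     k=int(idx.size), h2_grs=h2, removed=removed)


# ---------------------------------------------------------------------------
# conditional independence
# ---------------------------------------------------------------------------

def conditional_independence(
    beta_model1: float, beta_model2: float, p_lead_model2: float,
    max_change: float = 0.20, alpha: float = 0.05,
) -> bool:
    """Lead-SNP effect is independent of a conditioning proxy iff it changes
    by at most 20% between the unconditional and conditional models and
    stays nominally significant."""
    if beta_model1 == 0:
        raise ValueError("beta_model1 must be non-zero")
    rel_change = abs(beta_model2 - beta_model1) / abs(beta_model1)
    return bool(rel_change <= max_change and p_lead_model2 < alpha)


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------

@dataclass
class PowerSpec:
    """Parameters of a chi-square GWAS power calculation.

    NCP = n * 2 f (1 - f) * b^2 * r2 for an additive effect of b SD units
    at effect-allele frequency f with imputation quality r2.
    """

    n: int
    maf: float
    r2: float = 1.0
    alpha: float = 5e-8
    effect: float = float("nan")
    power: float = float("nan")

    @property
    def ncp(self) -> float:
        return self.n * 2.0 * self.maf * (1.0 - self.maf) * self.effect**2 * self.r2

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 < self.maf < 1.0:
            raise ValueError("maf must be in (0, 1)")
        if not 0.0 < self.r2 <= 1.0:
            raise ValueError("r2 must be in (0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def power_analysis(spec: PowerSpec, mode: str = "power_at_effect",
                   target_power: float = 0.80) -> PowerSpec:
    """Fill in the missing field of a power specification.

    ``power_at_effect``: power of the 1-df chi-square association test at
    ``spec.effect``.  ``min_detectable_effect``: smallest effect (SD units,
    bisection on (0, 5]) giving ``target_power``.
    """
    spec.validate()
    crit = stats.chi2.isf(spec.alpha, 1)

    def power_at(b: float) -> float:
        ncp = spec.n * 2.0 * spec.maf * (1.0 - spec.maf) * b**2 * spec.r2
        return float(stats.ncx2.sf(crit, 1, ncp)) if ncp > 0 \
            else float(stats.chi2.sf(crit, 1))

    if mode == "power_at_effect":
        if not np.isfinite(spec.effect):
            raise ValueError("spec.effect must be set for power_at_effect")
        spec.power = power_at(spec.effect)
        return spec
    if mode == "min_detectable_effect":
        if not 0.0 < target_power < 1.0:
            raise ValueError("target power must be in (0, 1)")
        if power_at(5.0) < target_power:
            raise ValueError("target power unattainable for effects up to 5 SD")
        spec.effect = float(optimize.brentq(
            lambda b: power_at(b) - target_power, 1e-12, 5.0, xtol=1e-10))
        spec.power = target_power
        return spec
    raise ValueError(f"unknown mode {mode!r}")
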
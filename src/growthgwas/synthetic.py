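"""Synthetic multi-study growth cohorts with known genetic ground truth.

The generator emulates the data structure of a multi-cohort longitudinal
child-growth GWAS: term-born singletons (gestational age 37-41 completed
weeks), an irregular visit schedule from birth to 13 years with per-visit
dropout, infancy and childhood log-BMI trajectories with per-child random
intercept and slope, Reed1-shaped height in the first two years (weight is
derived from BMI and height so the three measurements are always mutually
consistent), Hardy-Weinberg genotypes at configurable allele frequencies,
and SNP effects injected on the *latent* derived traits in SD units, with
optional between-study heterogeneity of the injected effects.

The generating fixed effects were chosen once by least-squares fit to
reference median growth (BMI peaking near 17.6 kg/m^2 at ~0.76 y, rebounding
near 15.4 kg/m^2 at ~5.1 y; height 50 -> 86.5 cm over 0-24 months), so the
latent population has a realistic adiposity peak and rebound.

Effect injection is exact on the analysis scale of each trait:

* ``bmi_ap`` / ``bmi_ar`` — shift the infancy / childhood random intercept;
  additive on log(BMI) at the extremum, whose age does not move.
* ``pwv`` — shift both models' intercepts by the same amount, which scales
  the whole weight curve (weight = BMI * height^2) and therefore scales the
  peak weight velocity; exact on log(PWV).
* ``phv`` — shift the subject's Reed1 linear slope by
  phv * (exp(delta) - 1), which shifts the velocity curve uniformly; exact
  on log(PHV).
* ``age_ap`` / ``age_ar`` — re-solve the random age slope so the stationary
  point of the child's log-BMI cubic moves by exactly the target amount
  (interior optima; subjects whose extremum sits on the window boundary are
  left unshifted).

The SD-unit scale for an effect is the within-study standard deviation of
the pre-injection latent trait on its analysis scale (log for all traits
except the two ages).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import growth
from .traits import TRAITS, LOG_TRAITS

logger = logging.getLogger(__name__)

DEFAULT_SEED = 20190904

#: target visit ages (years) with per-visit dropout probability; emulates a
#: child-health-clinic schedule dense in infancy and sparser in childhood
DEFAULT_VISIT_SCHEDULE: tuple[tuple[float, float], ...] = tuple(
    (age, 0.15)
    for age in (0.0, 0.04, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0,
                5.0, 6.0, 7.0, 8.0, 10.0, 13.0)
)

DEFAULT_GA_DISTRIBUTION: dict[int, float] = {37: 0.08, 38: 0.18, 39: 0.30, 40: 0.30, 41: 0.14}

# --- generating (true) growth parameters -----------------------------------

#: infancy log-BMI cubic in centered age (b0, b1, b2, b3) plus sex effect
INFANCY_TRUE = {"b0": 2.8684, "b1": 0.0051, "b2": -0.3284, "b3": 0.2962, "b_sex": 0.012}
#: childhood log-BMI cubic plus sex, age*sex, age^2*sex effects
CHILDHOOD_TRUE = {
    "b0": 2.7528, "b1": 0.016767, "b2": 0.0033073, "b3": -0.00021233,
    "b_sex": 0.008, "b_age_sex": 0.0015, "b_age2_sex": -0.0001,
}
#: covariance of the infancy random intercept/slope (u0, u1)
INFANCY_RE_COV = np.array([[0.08**2, -0.2 * 0.08 * 0.04], [-0.2 * 0.08 * 0.04, 0.04**2]])
#: covariance of the childhood random intercept/slope (v0, v1)
CHILDHOOD_RE_COV = np.array([[0.07**2, -0.1 * 0.07 * 0.006], [-0.1 * 0.07 * 0.006, 0.006**2]])
#: gestational-age effect on the infancy log-BMI intercept, per week from 39
INFANCY_GA_EFFECT = 0.008

#: Reed1 height truth (a, b, c, d), months / cm; interior velocity peak
HEIGHT_REED1_TRUE = {"a": 52.10, "b": 0.645, "c": 5.954, "d": 1.504}
HEIGHT_SEX_SHIFT = {"a": 0.8, "b": 0.01}           # boys taller, slightly faster
HEIGHT_GA_EFFECT = 0.7                             # cm per GA week from 39
HEIGHT_RE_COV = np.array([[2.0**2, 0.3 * 2.0 * 0.08], [0.3 * 2.0 * 0.08, 0.08**2]])
#: linear height growth beyond 24 months, cm per month
CHILD_HEIGHT_SLOPE = 0.5

#: latent PWV is evaluated on the infancy weight curve over this window
#: (months); the peak sits near 1 month, far from either edge
LATENT_PWV_WINDOW = (0.25, 18.0)


@dataclass(frozen=True)
class SnpSpec:
    snp_id: str
    chrom: str
    pos: int                      # 1-based
    effect_allele: str
    other_allele: str
    maf: float


@dataclass(frozen=True)
class CausalEffect:
    trait: str                    # one of TRAITS
    beta: float                   # SD units of the derived trait per effect allele


DEFAULT_SNP_PANEL: tuple[SnpSpec, ...] = (
    SnpSpec("rs_sim01", "1", 65430991, "G", "A", 0.22),
    SnpSpec("rs_sim02", "2", 614210, "G", "A", 0.12),
    SnpSpec("rs_sim03", "4", 45180510, "G", "A", 0.35),
    SnpSpec("rs_sim04", "5", 96323352, "A", "G", 0.21),
    SnpSpec("rs_sim05", "6", 50845193, "A", "G", 0.24),
    SnpSpec("rs_sim06", "11", 85406487, "C", "T", 0.25),
    SnpSpec("rs_sim07", "16", 53767042, "C", "T", 0.25),
    SnpSpec("rs_sim08", "5", 36497552, "G", "A", 0.31),
)


@dataclass
class CohortConfig:
    """Parameters of one simulated study (or a set of identical studies)."""

    n_individuals: int = 1500
    n_studies: int = 4
    visit_schedule: tuple[tuple[float, float], ...] = DEFAULT_VISIT_SCHEDULE
    ga_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_GA_DISTRIBUTION))
    sex_ratio: float = 0.5        # fraction male
    snp_panel: tuple[SnpSpec, ...] = DEFAULT_SNP_PANEL
    causal_effects: dict[str, CausalEffect] = field(default_factory=dict)
    between_study_sd: float = 0.0
    noise_log_bmi: float = 0.03
    noise_height_cm: float = 0.5
    #: multiplies all random-effect SDs; 0 gives a deterministic population
    random_effect_scale: float = 1.0
    seed: int = DEFAULT_SEED

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        for snp in self.snp_panel:
            if not 0.0 < snp.maf < 1.0:
                raise ValueError(f"MAF of {snp.snp_id} must be in (0, 1), got {snp.maf}")
        for age, p_drop in self.visit_schedule:
            if age < 0 or age > 13:
                raise ValueError(f"visit age {age} outside [0, 13] years")
            if not 0.0 <= p_drop <= 1.0:
                raise ValueError(f"dropout probability {p_drop} outside [0, 1]")
        ids = {s.snp_id for s in self.snp_panel}
        for snp_id, eff in self.causal_effects.items():
            if snp_id not in ids:
                raise ValueError(f"causal effect refers to unknown SNP {snp_id!r}")
            if eff.trait not in TRAITS:
                raise ValueError(
                    f"causal effect for {snp_id} targets unknown trait {eff.trait!r}")
            if not np.isfinite(eff.beta):
                raise ValueError(f"causal effect for {snp_id} is not finite")
        total = sum(self.ga_distribution.values())
        if not np.isclose(total, 1.0):
            raise ValueError("ga_distribution probabilities must sum to 1")
        for wk in self.ga_distribution:
            if not 37 <= wk <= 41:
                raise ValueError(f"gestational age {wk} outside 37-41 completed weeks")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")
        if self.between_study_sd < 0:
            raise ValueError("between_study_sd must be >= 0")
        if self.random_effect_scale < 0:
            raise ValueError("random_effect_scale must be >= 0")
        if self.noise_log_bmi < 0 or self.noise_height_cm < 0:
            raise ValueError("measurement noise SDs must be >= 0")


@dataclass
class GenotypeMatrix:
    """Dosages per subject x SNP, with panel metadata and info scores."""

    dosages: pd.DataFrame          # index subject id, columns snp id, values in [0, 2]
    panel: tuple[SnpSpec, ...]
    info: pd.Series                # per-SNP imputation info score in (0, 1]

    def __post_init__(self) -> None:
        vals = self.dosages.to_numpy()
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosages.columns)


@dataclass
class StudyData:
    """One simulated study: genotypes, subjects, measurements, ground truth."""

    study_id: str
    genotypes: GenotypeMatrix
    subjects: pd.DataFrame         # per-subject: sex, ga_weeks, true random effects
    measurements: pd.DataFrame     # long: id, study, sex, ga_weeks, age_years, ...
    truth: pd.DataFrame            # per-subject latent derived traits (post-injection)
    study_effects: dict[str, float]  # realized per-study causal betas


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    config: CohortConfig,
    subject_ids: list | None = None,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Draw hard-call genotypes as Binomial(2, MAF) per subject and SNP.

    SNPs are independent (no LD) and in Hardy-Weinberg proportions by
    construction.  Deterministic given the config seed (or a supplied rng).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if subject_ids is None:
        subject_ids = [f"S{i:05d}" for i in range(config.n_individuals)]
    mafs = np.array([s.maf for s in config.snp_panel])
    dos = rng.binomial(2, mafs, size=(len(subject_ids), len(mafs))).astype(float)
    df = pd.DataFrame(dos, index=pd.Index(subject_ids, name="id"),
                      columns=[s.snp_id for s in config.snp_panel])
    info = pd.Series(1.0, index=df.columns, name="info")
    return GenotypeMatrix(dosages=df, panel=config.snp_panel, info=info)


def hwe_chisq_p(dosages: np.ndarray) -> float:
    """Chi-square goodness-of-fit P value of hard calls against HWE."""
    d = np.round(np.asarray(dosages, dtype=float)).astype(int)
    counts = np.bincount(d, minlength=3)[:3]
    n = counts.sum()
    p = (counts[1] + 2 * counts[2]) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    chi2 = float(((counts - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, 1))


# ---------------------------------------------------------------------------
# latent curves and trait injection
# ---------------------------------------------------------------------------

def _latent_curves(subjects: pd.DataFrame) -> tuple[list, list]:
    """Individual true log-BMI curves for the infancy and childhood models."""
    inf, chi = [], []
    for sid, s in subjects.iterrows():
        sex = int(s["sex"])
        inf.append(growth.IndividualCurve(
            subject_id=sid, sex=sex,
            intercept=INFANCY_TRUE["b0"] + INFANCY_TRUE["b_sex"] * sex
            + INFANCY_GA_EFFECT * (s["ga_weeks"] - 39) + s["u0"],
            linear=INFANCY_TRUE["b1"] + s["u1"],
            quadratic=INFANCY_TRUE["b2"],
            cubic=INFANCY_TRUE["b3"],
            center_age=growth.INFANCY_CENTER_AGE,
        ))
        chi.append(growth.IndividualCurve(
            subject_id=sid, sex=sex,
            intercept=CHILDHOOD_TRUE["b0"] + CHILDHOOD_TRUE["b_sex"] * sex + s["v0"],
            linear=CHILDHOOD_TRUE["b1"] + CHILDHOOD_TRUE["b_age_sex"] * sex + s["v1"],
            quadratic=CHILDHOOD_TRUE["b2"] + CHILDHOOD_TRUE["b_age2_sex"] * sex,
            cubic=CHILDHOOD_TRUE["b3"],
            center_age=growth.CHILDHOOD_CENTER_AGE,
        ))
    return inf, chi


def _latent_height(subjects: pd.DataFrame, t_months: np.ndarray) -> np.ndarray:
    """True height (cm) for every subject (rows) at ages in months (cols)."""
    t = np.maximum(np.asarray(t_months, dtype=float), growth.REED1_MIN_AGE_MONTHS)
    a = subjects["h_a"].to_numpy()[:, None]
    b = subjects["h_b"].to_numpy()[:, None]
    c, d = HEIGHT_REED1_TRUE["c"], HEIGHT_REED1_TRUE["d"]
    base = a + b * t + c * np.log(t) + d / t
    over = t > 24.0
    if over.any():
        at24 = a + b * 24.0 + c * np.log(24.0) + d / 24.0
        base = np.where(over, at24 + CHILD_HEIGHT_SLOPE * (t - 24.0), base)
    return base


def _latent_pwv(subjects: pd.DataFrame) -> np.ndarray:
    """Latent peak weight velocity (kg/month) from the infancy weight curve."""
    tg = np.linspace(LATENT_PWV_WINDOW[0], LATENT_PWV_WINDOW[1], 2000)
    ages_y = tg / 12.0
    x = ages_y - growth.INFANCY_CENTER_AGE
    sex = subjects["sex"].to_numpy()[:, None]
    log_bmi = (
        INFANCY_TRUE["b0"] + INFANCY_TRUE["b_sex"] * sex
        + INFANCY_GA_EFFECT * (subjects["ga_weeks"].to_numpy()[:, None] - 39)
        + subjects["u0"].to_numpy()[:, None]
        + (INFANCY_TRUE["b1"] + subjects["u1"].to_numpy()[:, None]) * x
        + INFANCY_TRUE["b2"] * x**2 + INFANCY_TRUE["b3"] * x**3
    )
    h = _latent_height(subjects, tg)
    w = np.exp(log_bmi) * (h / 100.0) ** 2
    v = np.gradient(w, tg, axis=1)
    return v.max(axis=1)


def _latent_traits(subjects: pd.DataFrame) -> pd.DataFrame:
    """Latent (noise-free) derived traits for every subject."""
    inf, chi = _latent_curves(subjects)
    out = pd.DataFrame(index=subjects.index)
    ap = [growth.derive_ap(c) for c in inf]
    ar = [growth.derive_ar(c) for c in chi]
    out["age_ap"] = [e.age_years for e in ap]
    out["bmi_ap"] = [e.bmi for e in ap]
    out["age_ar"] = [e.age_years for e in ar]
    out["bmi_ar"] = [e.bmi for e in ar]
    c, d = HEIGHT_REED1_TRUE["c"], HEIGHT_REED1_TRUE["d"]
    out["phv"] = [
        growth.derive_peak_velocity(b, c, d)[0] for b in subjects["h_b"]
    ]
    out["pwv"] = _latent_pwv(subjects)
    return out


def _analysis_scale(trait: str, values: np.ndarray) -> np.ndarray:
    return np.log(values) if trait in LOG_TRAITS else values


def _inject_effect(subjects: pd.DataFrame, trait: str, delta: np.ndarray) -> None:
    """Shift latent parameters so the trait moves by ``delta`` per subject.

    ``delta`` is on the analysis scale (log for log-transformed traits).
    Modifies ``subjects`` in place.
    """
    if trait == "bmi_ap":
        subjects["u0"] += delta
    elif trait == "bmi_ar":
        subjects["v0"] += delta
    elif trait == "pwv":
        # scale the whole weight curve: exact multiplicative shift of PWV
        subjects["u0"] += delta
        subjects["v0"] += delta
    elif trait == "phv":
        c, dd = HEIGHT_REED1_TRUE["c"], HEIGHT_REED1_TRUE["d"]
        phv = np.array([
            growth.derive_peak_velocity(b, c, dd)[0] for b in subjects["h_b"]
        ])
        subjects["h_b"] += phv * np.expm1(delta)
    elif trait in ("age_ap", "age_ar"):
        inf, chi = _latent_curves(subjects)
        curves = inf if trait == "age_ap" else chi
        derive = growth.derive_ap if trait == "age_ap" else growth.derive_ar
        col = "u1" if trait == "age_ap" else "v1"
        new_u1 = subjects[col].to_numpy().copy()
        for i, curve in enumerate(curves):
            if delta[i] == 0.0:
                continue
            ext = derive(curve)
            if ext.boundary:
                continue  # no interior optimum to move
            x_new = ext.age_years + delta[i] - curve.center_age
            # stationarity at x_new: linear + 2*quad*x + 3*cubic*x^2 = 0
            lin_new = -(2.0 * curve.quadratic * x_new + 3.0 * curve.cubic * x_new**2)
            new_u1[i] += lin_new - curve.linear
        subjects[col] = new_u1
    else:  # pragma: no cover - guarded by CohortConfig.validate
        raise ValueError(f"cannot inject effects on trait {trait!r}")


# ---------------------------------------------------------------------------
# growth simulation
# ---------------------------------------------------------------------------

def simulate_growth(
    config: CohortConfig,
    genotypes: GenotypeMatrix,
    rng: np.random.Generator | None = None,
    study_id: str = "study1",
    study_shifts: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate subjects and longitudinal measurements for one study.

    Returns ``(subjects, measurements, truth)`` where ``truth`` holds the
    post-injection latent derived traits.  ``study_shifts`` adds a per-study
    perturbation to each causal effect (used by :func:`simulate_multi_study`).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    ids = list(genotypes.dosages.index)
    n = len(ids)

    sex = (rng.random(n) < config.sex_ratio).astype(int)  # 1 = male
    weeks = np.array(sorted(config.ga_distribution))
    probs = np.array([config.ga_distribution[w] for w in weeks])
    ga = rng.choice(weeks, size=n, p=probs)

    re2 = config.random_effect_scale**2
    u = rng.multivariate_normal(np.zeros(2), re2 * INFANCY_RE_COV, size=n)
    v = rng.multivariate_normal(np.zeros(2), re2 * CHILDHOOD_RE_COV, size=n)
    h = rng.multivariate_normal(
        [HEIGHT_REED1_TRUE["a"], HEIGHT_REED1_TRUE["b"]], re2 * HEIGHT_RE_COV, size=n)
    subjects = pd.DataFrame(
        {
            "study": study_id,
            "sex": sex,
            "ga_weeks": ga,
            "u0": u[:, 0], "u1": u[:, 1],
            "v0": v[:, 0], "v1": v[:, 1],
            "h_a": h[:, 0] + HEIGHT_SEX_SHIFT["a"] * sex + HEIGHT_GA_EFFECT * (ga - 39),
            "h_b": h[:, 1] + HEIGHT_SEX_SHIFT["b"] * sex,
        },
        index=pd.Index(ids, name="id"),
    )

    # inject causal SNP effects on the latent traits (age traits first so
    # later intercept shifts cannot be displaced)
    if config.causal_effects:
        base = _latent_traits(subjects)
        order = sorted(
            config.causal_effects.items(),
            key=lambda kv: kv[1].trait not in ("age_ap", "age_ar"),
        )
        for snp_id, eff in order:
            beta = eff.beta + (study_shifts or {}).get(snp_id, 0.0)
            sigma = float(np.std(_analysis_scale(eff.trait, base[eff.trait].to_numpy()),
                                 ddof=1))
            dose = genotypes.dosages[snp_id].to_numpy()
            _inject_effect(subjects, eff.trait, dose * beta * sigma)

    truth = _latent_traits(subjects)

    # realize visits and measurements
    inf_curves, chi_curves = _latent_curves(subjects)
    schedule = list(config.visit_schedule)
    ages = np.array([a for a, _ in schedule])
    drops = np.array([p for _, p in schedule])
    keep = rng.random((n, len(schedule))) >= drops  # True = attended

    rows = []
    for i, sid in enumerate(ids):
        vis = ages[keep[i]]
        if len(vis) == 0:
            continue
        x_inf = vis - growth.INFANCY_CENTER_AGE
        x_chi = vis - growth.CHILDHOOD_CENTER_AGE
        ci, cc = inf_curves[i], chi_curves[i]
        log_bmi = np.where(
            vis <= growth.INFANCY_AGE_RANGE[1],
            ci.intercept + ci.linear * x_inf + ci.quadratic * x_inf**2 + ci.cubic * x_inf**3,
            cc.intercept + cc.linear * x_chi + cc.quadratic * x_chi**2 + cc.cubic * x_chi**3,
        )
        log_bmi = log_bmi + rng.normal(0.0, config.noise_log_bmi, len(vis))
        height = (
            _latent_height(subjects.iloc[[i]], vis * 12.0)[0]
            + rng.normal(0.0, config.noise_height_cm, len(vis))
        )
        bmi = np.exp(log_bmi)
        weight = bmi * (height / 100.0) ** 2
        for age_y, w_kg, h_cm, b in zip(vis, weight, height, bmi):
            rows.append((sid, study_id, sex[i], ga[i], age_y, w_kg, h_cm, b))

    measurements = pd.DataFrame(
        rows,
        columns=["id", "study", "sex", "ga_weeks", "age_years",
                 "weight_kg", "height_cm", "bmi_kgm2"],
    )
    return subjects, measurements, truth


def simulate_study(
    config: CohortConfig, study_id: str, seed: int,
    study_shifts: dict[str, float] | None = None,
) -> StudyData:
    """Simulate genotypes + growth for one named study from one seed."""
    ss = np.random.SeedSequence(seed)
    rng_g, rng_p = (np.random.default_rng(s) for s in ss.spawn(2))
    ids = [f"{study_id}_{i:05d}" for i in range(config.n_individuals)]
    genotypes = simulate_genotypes(config, subject_ids=ids, rng=rng_g)
    subjects, measurements, truth = simulate_growth(
        config, genotypes, rng=rng_p, study_id=study_id, study_shifts=study_shifts)
    realized = {
        snp_id: eff.beta + (study_shifts or {}).get(snp_id, 0.0)
        for snp_id, eff in config.causal_effects.items()
    }
    return StudyData(
        study_id=study_id, genotypes=genotypes, subjects=subjects,
        measurements=measurements, truth=truth, study_effects=realized,
    )


def simulate_multi_study(config: CohortConfig) -> list[StudyData]:
    """Simulate ``config.n_studies`` independent cohorts.

    Each causal effect is perturbed per study by Normal(0, between_study_sd)
    so that downstream Cochran's Q behaves as expected: chi-square with k-1
    degrees of freedom when between_study_sd = 0, inflated otherwise.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(config.n_studies + 1)
    shift_rng = np.random.default_rng(seeds[-1])
    studies = []
    for j in range(config.n_studies):
        shifts = {
            snp_id: float(shift_rng.normal(0.0, config.between_study_sd))
            if config.between_study_sd > 0 else 0.0
            for snp_id in config.causal_effects
        }
        studies.append(
            simulate_study(config, f"study{j + 1}", int(seeds[j]), shifts))
    logger.info("simulated %d studies of %d subjects", config.n_studies,
                config.n_individuals)
    return studies
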
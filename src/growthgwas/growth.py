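"""Growth-curve models and derivation of the six early-growth traits.

Two linear mixed models are fitted to log(BMI), each with a random intercept
and a random linear age slope per child:

* infancy (2 weeks - 18 months, age centered at 0.75 years)::

      log(BMI) = b0 + b1*a + b2*a^2 + b3*a^3 + b4*Sex + u0 + u1*a + eps

* childhood (18 months - 13 years, age centered at 7.25 years), which adds
  ``b5*a*Sex + b6*a^2*Sex`` to the fixed effects.

The adiposity peak (AP) and rebound (AR) are the extrema of each child's
predicted log-BMI curve inside fixed age windows.  Peak height and weight
velocities come from a Reed1 curve ``y(t) = a + b*t + c*ln(t) + d/t``
(t in months) fitted to 0-24 month measurements; the velocity is
``v(t) = b + c/t - d/t^2`` with an interior stationary point at
``t* = 2d/c`` (a maximum iff d > 0).

The Reed1 curve is linear in its parameters, so instead of a full nonlinear
random-effects fit we use a two-stage scheme: the shape parameters (c, d)
are shared within a sex stratum and estimated by within-subject partitioned
regression (each subject keeps its own intercept and linear slope), then
(a, b) are estimated per subject by least squares given (c, d).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .traits import (
    AP_WINDOW_YEARS,
    AR_WINDOW_YEARS,
    CHILDHOOD_AGE_RANGE,
    CHILDHOOD_CENTER_AGE,
    INFANCY_AGE_RANGE,
    INFANCY_CENTER_AGE,
    MIN_MEASUREMENTS,
    REED1_AGE_RANGE_YEARS,
    REED1_MIN_AGE_MONTHS,
    VELOCITY_WINDOW_MONTHS,
)

logger = logging.getLogger(__name__)

MIN_SUBJECTS = 20

INFANCY_PARAM_NAMES = ("b0", "b1", "b2", "b3", "b_sex")
CHILDHOOD_PARAM_NAMES = ("b0", "b1", "b2", "b3", "b_sex", "b_age_sex", "b_age2_sex")


# ---------------------------------------------------------------------------
# BMI mixed models
# ---------------------------------------------------------------------------

@dataclass
class BmiModelFit:
    """A fitted log-BMI mixed model with per-subject random effects."""

    stage: str                      # "infancy" or "childhood"
    params: np.ndarray              # fixed effects, order as param_names
    params_se: np.ndarray           # standard errors of the fixed effects
    param_names: tuple[str, ...]
    cov_re: np.ndarray              # 2x2 covariance of (u0, u1)
    resid_var: float
    center_age: float               # years
    loglike: float
    random_effects: pd.DataFrame    # index subject id, columns u0, u1
    n_subjects: int
    n_obs: int
    converged: bool

    def __post_init__(self) -> None:
        eig = np.linalg.eigvalsh(np.asarray(self.cov_re, dtype=float))
        if eig.min() < -1e-8:
            raise ValueError("random-effect covariance is not positive semi-definite")
        if self.resid_var < 0:
            raise ValueError("residual variance must be non-negative")


@dataclass(frozen=True)
class IndividualCurve:
    """One child's predicted log-BMI polynomial in centered age."""

    subject_id: object
    sex: int
    intercept: float     # b0 + b_sex*sex + u0
    linear: float        # b1 (+ b_age_sex*sex) + u1
    quadratic: float     # b2 (+ b_age2_sex*sex)
    cubic: float         # b3
    center_age: float

    def log_bmi(self, age_years):
        """Predicted log(BMI) at an age in years."""
        x = np.asarray(age_years, dtype=float) - self.center_age
        return self.intercept + self.linear * x + self.quadratic * x**2 + self.cubic * x**3


@dataclass(frozen=True)
class Extremum:
    age_years: float
    bmi: float
    boundary: bool


def _model_frame(measurements: pd.DataFrame, lo: float, hi: float) -> pd.DataFrame:
    required = {"id", "sex", "age_years", "weight_kg", "height_cm"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurements table is missing columns {sorted(missing)}")
    m = measurements.loc[
        (measurements["age_years"] > lo) & (measurements["age_years"] <= hi)
    ].copy()
    m["bmi"] = m["weight_kg"] / (m["height_cm"] / 100.0) ** 2
    counts = m.groupby("id")["age_years"].size()
    keep = counts.index[counts >= MIN_MEASUREMENTS]
    m = m[m["id"].isin(keep)]
    return m


def _fit_bmi_model(measurements: pd.DataFrame, stage: str) -> BmiModelFit:
    if stage == "infancy":
        lo, hi = INFANCY_AGE_RANGE
        center = INFANCY_CENTER_AGE
        names = INFANCY_PARAM_NAMES
    else:
        lo, hi = CHILDHOOD_AGE_RANGE
        center = CHILDHOOD_CENTER_AGE
        names = CHILDHOOD_PARAM_NAMES

    m = _model_frame(measurements, lo, hi)
    ids = m["id"].to_numpy()
    n_subj = len(np.unique(ids))
    if n_subj < MIN_SUBJECTS:
        raise ValueError(
            f"{stage} model needs at least {MIN_SUBJECTS} subjects with "
            f">= {MIN_MEASUREMENTS} in-window measurements; got {n_subj}"
        )

    y = np.log(m["bmi"].to_numpy())
    x = m["age_years"].to_numpy() - center
    sex = m["sex"].to_numpy(dtype=float)
    cols = [np.ones_like(x), x, x**2, x**3, sex]
    if stage == "childhood":
        cols += [x * sex, x**2 * sex]
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"{stage} model design matrix is rank deficient")

    # OLS first: starting point, and the exact answer in the noiseless limit
    ols_beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    ols_resid = y - X @ ols_beta
    ols_var = float(ols_resid @ ols_resid) / max(len(y) - X.shape[1], 1)

    if ols_var < 1e-12:
        # degenerate noiseless data: the mixed model is unidentified, the
        # OLS fit is exact and all random effects are zero
        re = pd.DataFrame(
            0.0, index=pd.Index(np.unique(ids), name="id"), columns=["u0", "u1"]
        )
        return BmiModelFit(
            stage=stage,
            params=ols_beta,
            params_se=np.zeros_like(ols_beta),
            param_names=names,
            cov_re=np.zeros((2, 2)),
            resid_var=0.0,
            center_age=center,
            loglike=np.inf,
            random_effects=re,
            n_subjects=n_subj,
            n_obs=len(y),
            converged=True,
        )

    exog_re = np.column_stack([np.ones_like(x), x])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model = MixedLM(y, X, groups=ids, exog_re=exog_re)
        result = model.fit(reml=False, method=["lbfgs", "bfgs"], maxiter=500)

    re_dict = result.random_effects
    re = pd.DataFrame.from_dict(re_dict, orient="index")
    re.columns = ["u0", "u1"]
    re.index.name = "id"

    cov_re = np.asarray(result.cov_re)
    # clip tiny negative eigenvalues arising from boundary solutions
    eig, vec = np.linalg.eigh(cov_re)
    if eig.min() < 0 and eig.min() > -1e-8:
        cov_re = (vec * np.clip(eig, 0.0, None)) @ vec.T

    return BmiModelFit(
        stage=stage,
        params=np.asarray(result.fe_params, dtype=float),
        params_se=np.asarray(result.bse_fe, dtype=float),
        param_names=names,
        cov_re=cov_re,
        resid_var=float(result.scale),
        center_age=center,
        loglike=float(result.llf),
        random_effects=re,
        n_subjects=n_subj,
        n_obs=len(y),
        converged=bool(result.converged),
    )


def fit_infancy_bmi_model(measurements: pd.DataFrame) -> BmiModelFit:
    """ML fit of the infancy log-BMI mixed model (2 weeks - 18 months).

    ``measurements`` is a long table with columns id, sex, age_years,
    weight_kg, height_cm.  Subjects need at least three in-window
    measurements; fewer than 20 usable subjects is an error.
    """
    return _fit_bmi_model(measurements, "infancy")


def fit_childhood_bmi_model(measurements: pd.DataFrame) -> BmiModelFit:
    """ML fit of the childhood log-BMI mixed model (18 months - 13 years)."""
    return _fit_bmi_model(measurements, "childhood")


def bmi_loglike_at(measurements: pd.DataFrame, stage: str,
                   params: np.ndarray, cov_re: np.ndarray,
                   resid_var: float) -> float:
    """Profile-free log-likelihood of a log-BMI mixed model at given
    parameters (used to check that the ML fit dominates the truth)."""
    if stage == "infancy":
        lo, hi = INFANCY_AGE_RANGE
        center = INFANCY_CENTER_AGE
    else:
        lo, hi = CHILDHOOD_AGE_RANGE
        center = CHILDHOOD_CENTER_AGE
    m = _model_frame(measurements, lo, hi)
    y = np.log(m["bmi"].to_numpy())
    x = m["age_years"].to_numpy() - center
    sex = m["sex"].to_numpy(dtype=float)
    cols = [np.ones_like(x), x, x**2, x**3, sex]
    if stage == "childhood":
        cols += [x * sex, x**2 * sex]
    X = np.column_stack(cols)
    resid = y - X @ np.asarray(params, dtype=float)
    ll = 0.0
    cov_re = np.asarray(cov_re, dtype=float)
    for _, idx in m.groupby("id").indices.items():
        Z = np.column_stack([np.ones(len(idx)), x[idx]])
        V = Z @ cov_re @ Z.T + resid_var * np.eye(len(idx))
        sign, logdet = np.linalg.slogdet(V)
        r = resid[idx]
        ll += -0.5 * (len(idx) * np.log(2 * np.pi) + logdet + r @ np.linalg.solve(V, r))
    return float(ll)


def individual_curves(fit: BmiModelFit, sex_by_subject: pd.Series) -> list[IndividualCurve]:
    """Build each subject's effective log-BMI polynomial from a model fit.

    ``sex_by_subject`` maps subject id -> sex (0 female / 1 male) and must
    cover every subject in the fit's random effects.
    """
    p = dict(zip(fit.param_names, fit.params))
    curves = []
    for sid, row in fit.random_effects.iterrows():
        sex = int(sex_by_subject[sid])
        lin = p["b1"] + row["u1"]
        quad = p["b2"]
        if fit.stage == "childhood":
            lin += p["b_age_sex"] * sex
            quad += p["b_age2_sex"] * sex
        curves.append(
            IndividualCurve(
                subject_id=sid,
                sex=sex,
                intercept=p["b0"] + p["b_sex"] * sex + row["u0"],
                linear=lin,
                quadratic=quad,
                cubic=p["b3"],
                center_age=fit.center_age,
            )
        )
    return curves


# ---------------------------------------------------------------------------
# AP / AR derivation
# ---------------------------------------------------------------------------

def _poly_extremum(curve: IndividualCurve, window: tuple[float, float],
                   mode: str) -> Extremum:
    for name in ("intercept", "linear", "quadratic", "cubic"):
        if not np.isfinite(getattr(curve, name)):
            raise ValueError(f"non-finite coefficient {name!r} for subject {curve.subject_id}")
    lo = window[0] - curve.center_age
    hi = window[1] - curve.center_age

    # stationary points: linear + 2*quad*x + 3*cubic*x^2 = 0
    a2, a1, a0 = 3.0 * curve.cubic, 2.0 * curve.quadratic, curve.linear
    roots: list[float] = []
    if abs(a2) > 1e-14:
        disc = a1 * a1 - 4.0 * a2 * a0
        if disc >= 0:
            s = np.sqrt(disc)
            roots = [(-a1 - s) / (2 * a2), (-a1 + s) / (2 * a2)]
    elif abs(a1) > 1e-14:
        roots = [-a0 / a1]

    candidates = [lo, hi] + [r for r in roots if lo < r < hi]
    xs = np.array(sorted(candidates))
    vals = curve.intercept + curve.linear * xs + curve.quadratic * xs**2 + curve.cubic * xs**3
    sign = 1.0 if mode == "max" else -1.0
    best = int(np.argmax(sign * vals))  # argmax takes the first (earliest age) on ties
    x_best = xs[best]
    boundary = bool(np.isclose(x_best, lo) or np.isclose(x_best, hi))
    return Extremum(
        age_years=float(x_best + curve.center_age),
        bmi=float(np.exp(vals[best])),
        boundary=boundary,
    )


def derive_ap(curve: IndividualCurve) -> Extremum:
    """Adiposity peak: maximum predicted BMI on 0.25-1.25 years.

    Candidates are the interior stationary points of the cubic plus the two
    window endpoints; ties go to the earliest age, and the boundary flag is
    set when the maximum sits at an endpoint.
    """
    return _poly_extremum(curve, AP_WINDOW_YEARS, "max")


def derive_ar(curve: IndividualCurve) -> Extremum:
    """Adiposity rebound: minimum predicted BMI on 2.5-8.5 years."""
    return _poly_extremum(curve, AR_WINDOW_YEARS, "min")


# ---------------------------------------------------------------------------
# Reed1 model and peak velocities
# ---------------------------------------------------------------------------

@dataclass
class Reed1Fit:
    """Two-stage Reed1 fit: shared (c, d) per sex stratum, (a, b) per subject."""

    measure: str                 # "height_cm" or "weight_kg"
    sex_stratum: int
    c: float
    d: float
    subjects: pd.DataFrame       # index id; columns a, b, resid_sd, n_obs
    missing: list = field(default_factory=list)  # ids with <3 usable points

    def curve(self, subject_id, t_months):
        row = self.subjects.loc[subject_id]
        t = np.maximum(np.asarray(t_months, dtype=float), REED1_MIN_AGE_MONTHS)
        return row["a"] + row["b"] * t + self.c * np.log(t) + self.d / t


def reed1_velocity(b: float, c: float, d: float, t_months):
    """Analytic Reed1 growth velocity v(t) = b + c/t - d/t^2 (per month)."""
    t = np.asarray(t_months, dtype=float)
    return b + c / t - d / t**2


def fit_reed1(measurements: pd.DataFrame, measure: str, sex_stratum: int) -> Reed1Fit:
    """Fit the Reed1 model to 0-24 month height or weight measurements.

    Ages are floored at 0.25 months so ln(t) and 1/t are defined at birth.
    Stage 1 estimates the shared (c, d) by pooled regression of
    within-subject residuals (each subject's own intercept and linear trend
    partialled out); stage 2 estimates (a, b) per subject given (c, d).
    Subjects with fewer than three usable timepoints are listed in
    ``missing`` and not fitted.
    """
    if measure not in ("height_cm", "weight_kg"):
        raise ValueError(f"measure must be 'height_cm' or 'weight_kg', got {measure!r}")
    lo_y, hi_y = REED1_AGE_RANGE_YEARS
    m = measurements.loc[
        (measurements["sex"] == sex_stratum)
        & (measurements["age_years"] >= lo_y)
        & (measurements["age_years"] <= hi_y)
    ]
    t_all = np.maximum(m["age_years"].to_numpy() * 12.0, REED1_MIN_AGE_MONTHS)
    y_all = m[measure].to_numpy(dtype=float)
    ids = m["id"].to_numpy()

    groups = pd.Series(np.arange(len(m)), index=ids).groupby(level=0).indices
    usable: dict = {}
    missing: list = []
    for sid, idx in groups.items():
        t = t_all[idx]
        if len(idx) < MIN_MEASUREMENTS or np.ptp(t) < 1e-9:
            missing.append(sid)
        else:
            usable[sid] = idx
    if not usable:
        raise ValueError("no subject has >= 3 usable measurements for the Reed1 fit")

    # stage 1: partial each variable on the per-subject {1, t} design, then
    # pool-regress residual y on residual [ln t, 1/t] -> shared (c, d)
    rows_y, rows_b = [], []
    for sid, idx in usable.items():
        t = t_all[idx]
        D = np.column_stack([np.ones(len(t)), t])
        V = np.column_stack([y_all[idx], np.log(t), 1.0 / t])
        coef, _, _, _ = np.linalg.lstsq(D, V, rcond=None)
        R = V - D @ coef
        rows_y.append(R[:, 0])
        rows_b.append(R[:, 1:])
    ry = np.concatenate(rows_y)
    RB = np.vstack(rows_b)
    cd, _, _, _ = np.linalg.lstsq(RB, ry, rcond=None)
    c, d = float(cd[0]), float(cd[1])

    # stage 2: per-subject (a, b) given (c, d)
    recs = {}
    for sid, idx in usable.items():
        t = t_all[idx]
        z = y_all[idx] - c * np.log(t) - d / t
        D = np.column_stack([np.ones(len(t)), t])
        ab, _, _, _ = np.linalg.lstsq(D, z, rcond=None)
        resid = z - D @ ab
        dof = max(len(t) - 2, 1)
        recs[sid] = (ab[0], ab[1], float(np.sqrt(resid @ resid / dof)), len(t))
    subjects = pd.DataFrame.from_dict(
        recs, orient="index", columns=["a", "b", "resid_sd", "n_obs"]
    )
    subjects.index.name = "id"
    return Reed1Fit(
        measure=measure, sex_stratum=sex_stratum, c=c, d=d,
        subjects=subjects, missing=missing,
    )


def derive_peak_velocity(
    b: float, c: float, d: float,
    window_months: tuple[float, float] = VELOCITY_WINDOW_MONTHS,
) -> tuple[float, float, bool]:
    """Peak of the Reed1 velocity curve on a window of ages in months.

    Returns ``(pv, age_at_pv_months, boundary_flag)``.  The interior
    stationary point t* = 2d/c is a candidate only when it lies inside the
    window and is a maximum (d > 0); otherwise the peak is at an endpoint.
    """
    lo, hi = window_months
    if not (0.0 < lo < hi <= 24.0 + 1e-9):
        raise ValueError(f"velocity window must lie inside (0, 24] months, got {window_months}")
    if c == 0.0 and d == 0.0:
        return float(b), float(lo), False
    candidates = [lo, hi]
    if c != 0.0:
        t_star = 2.0 * d / c
        if lo < t_star < hi and d > 0:
            candidates.append(t_star)
    ts = np.array(sorted(candidates))
    vs = reed1_velocity(b, c, d, ts)
    best = int(np.argmax(vs))
    t_best = ts[best]
    boundary = bool(np.isclose(t_best, lo) or np.isclose(t_best, hi))
    return float(vs[best]), float(t_best), boundary


# ---------------------------------------------------------------------------
# Orchestration: the six traits per subject
# ---------------------------------------------------------------------------

def derive_all_traits(
    measurements: pd.DataFrame,
    velocity_window: tuple[float, float] = VELOCITY_WINDOW_MONTHS,
    models: tuple[str, ...] = ("infancy", "childhood", "reed1"),
) -> tuple[pd.DataFrame, dict]:
    """Fit all growth models and derive the six traits for every subject.

    Returns a wide per-subject table (six trait columns, matching
    ``*_boundary`` flags, sex and gestational age carried through; subjects
    without enough data for a model get NaN in that model's traits) and a
    dict with the underlying fits.  ``models`` restricts which growth models
    are fitted (traits of unfitted models stay missing).
    """
    subj = measurements.drop_duplicates("id").set_index("id")
    out = pd.DataFrame(index=subj.index)
    out["sex"] = subj["sex"]
    if "ga_weeks" in subj.columns:
        out["ga_weeks"] = subj["ga_weeks"]
    if "study" in subj.columns:
        out["study"] = subj["study"]

    fits: dict = {}
    for trait in ("phv", "pwv", "age_ap", "bmi_ap", "age_ar", "bmi_ar"):
        out[trait] = np.nan
    for flag in ("ap_boundary", "ar_boundary", "phv_boundary", "pwv_boundary"):
        out[flag] = pd.array([None] * len(out), dtype="boolean")

    if "infancy" in models:
        infancy = fit_infancy_bmi_model(measurements)
        fits["infancy"] = infancy
        for curve in individual_curves(infancy, subj["sex"]):
            ap = derive_ap(curve)
            out.loc[curve.subject_id, ["age_ap", "bmi_ap"]] = (ap.age_years, ap.bmi)
            out.loc[curve.subject_id, "ap_boundary"] = ap.boundary

    if "childhood" in models:
        childhood = fit_childhood_bmi_model(measurements)
        fits["childhood"] = childhood
        for curve in individual_curves(childhood, subj["sex"]):
            ar = derive_ar(curve)
            out.loc[curve.subject_id, ["age_ar", "bmi_ar"]] = (ar.age_years, ar.bmi)
            out.loc[curve.subject_id, "ar_boundary"] = ar.boundary

    if "reed1" in models:
        for measure, trait, flag in (
            ("height_cm", "phv", "phv_boundary"),
            ("weight_kg", "pwv", "pwv_boundary"),
        ):
            for sex in sorted(subj["sex"].unique()):
                fit = fit_reed1(measurements, measure, int(sex))
                fits[f"reed1_{measure}_sex{int(sex)}"] = fit
                for sid, row in fit.subjects.iterrows():
                    pv, _, boundary = derive_peak_velocity(
                        row["b"], fit.c, fit.d, velocity_window
                    )
                    out.loc[sid, trait] = pv
                    out.loc[sid, flag] = boundary

    for trait in ("phv", "pwv", "age_ap", "bmi_ap", "age_ar", "bmi_ar"):
        out[f"{trait}_missing"] = out[trait].isna()
    logger.info("derived traits for %d subjects (models: %s)",
                len(out), ", ".join(models))
    return out, fits
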
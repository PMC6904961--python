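"""Shared definitions for the six early-growth traits.

The traits are derived per child from fitted growth curves:

* ``phv`` / ``pwv`` — peak height / weight velocity in infancy (cm/month,
  kg/month), from a Reed1 curve fitted on 0-24 months.
* ``age_ap`` / ``bmi_ap`` — age (years) and BMI (kg/m^2) at the adiposity
  peak, the maximum of the infancy BMI trajectory on 0.25-1.25 years.
* ``age_ar`` / ``bmi_ar`` — age and BMI at the adiposity rebound, the
  minimum of the childhood BMI trajectory on 2.5-8.5 years.

Analysis conventions applied downstream: every trait except the two ages is
natural-log transformed before z-scoring, and every trait except the two
rebound traits is adjusted for gestational age (all are adjusted for sex).
"""

from __future__ import annotations

TRAITS: tuple[str, ...] = ("phv", "pwv", "age_ap", "bmi_ap", "age_ar", "bmi_ar")

#: traits natural-log transformed before z-scoring (all but the two ages)
LOG_TRAITS = frozenset({"phv", "pwv", "bmi_ap", "bmi_ar"})

#: traits whose association model is adjusted for gestational age in
#: addition to sex (the rebound traits are adjusted for sex only)
GA_ADJUSTED_TRAITS = frozenset({"phv", "pwv", "age_ap", "bmi_ap"})

# search windows for the curve extrema
AP_WINDOW_YEARS = (0.25, 1.25)
AR_WINDOW_YEARS = (2.5, 8.5)
VELOCITY_WINDOW_MONTHS = (0.25, 24.0)

# fitting windows and centering ages of the two BMI models
INFANCY_AGE_RANGE = (14.0 / 365.25, 1.5)   # (2 weeks, 18 months]
CHILDHOOD_AGE_RANGE = (1.5, 13.0)          # (18 months, 13 years]
INFANCY_CENTER_AGE = 0.75
CHILDHOOD_CENTER_AGE = 7.25

# Reed1 fitting window (years) and the floor applied to age in months so
# that ln(t) and 1/t are defined at birth
REED1_AGE_RANGE_YEARS = (0.0, 2.0)
REED1_MIN_AGE_MONTHS = 0.25

#: minimum usable measurements per subject, per fitted model
MIN_MEASUREMENTS = 3

SEX_FEMALE = 0
SEX_MALE = 1


def covariate_set(trait: str) -> str:
    """Return the covariate rule for a trait: ``"sex+ga"`` or ``"sex"``."""
    _check_trait(trait)
    return "sex+ga" if trait in GA_ADJUSTED_TRAITS else "sex"


def transform_of(trait: str) -> str:
    """Return the transform applied before z-scoring: ``"log"`` or ``"none"``."""
    _check_trait(trait)
    return "log" if trait in LOG_TRAITS else "none"


def _check_trait(trait: str) -> None:
    if trait not in TRAITS:
        raise ValueError(f"unknown trait {trait!r}; expected one of {TRAITS}")
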
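import numpy as np
import pandas as pd
import pytest

from growthgwas import CausalEffect, CohortConfig, derive_all_traits, simulate_study


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20190904)


@pytest.fixture(scope="session")
def small_study():
    """One simulated 400-child study with a strong BMI-AP effect."""
    cfg = CohortConfig(
        n_individuals=400, n_studies=1,
        causal_effects={"rs_sim01": CausalEffect("bmi_ap", 0.35)},
        seed=20190904,
    )
    return simulate_study(cfg, "study1", 20190904)


@pytest.fixture(scope="session")
def small_derived(small_study):
    """Derived traits + growth-model fits for the shared small study."""
    derived, fits = derive_all_traits(small_study.measurements)
    return derived, fits


@pytest.fixture(scope="session")
def null_study():
    """A 500-child study with no causal SNPs (for null calibration)."""
    cfg = CohortConfig(n_individuals=500, n_studies=1, seed=77)
    return simulate_study(cfg, "nullstudy", 77)


def reed1_measurements(params_by_subject, t_months, sex=0, noise_sd=0.0,
                       rng=None, measure="weight_kg"):
    """Build a measurements frame from explicit Reed1 parameters."""
    rows = []
    for sid, (a, b, c, d) in params_by_subject.items():
        t = np.asarray(t_months, dtype=float)
        y = a + b * t + c * np.log(t) + d / t
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, len(t))
        for ti, yi in zip(t, y):
            rows.append({
                "id": sid, "sex": sex, "ga_weeks": 40, "study": "s",
                "age_years": ti / 12.0, measure: yi,
                ("height_cm" if measure == "weight_kg" else "weight_kg"): 50.0,
            })
    return pd.DataFrame(rows)
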
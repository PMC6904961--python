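"""Trait preparation, OLS association, QC filtering and genomic control."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from growthgwas import (
    QCThresholds,
    TraitVector,
    association_scan,
    genomic_control,
    prepare_trait,
    qc_filter,
    run_snp_association,
)
from growthgwas.assoc import CHI2_1_MEDIAN


def _trait_vector(values, trait="bmi_ap", covariates="sex+ga"):
    return TraitVector(trait=trait, values=pd.Series(values, dtype=float),
                       transform="none", covariates=covariates)


def _covars(n, rng):
    return pd.DataFrame({
        "sex": rng.integers(0, 2, n),
        "ga_weeks": rng.integers(37, 42, n),
    })


class TestPrepareTrait:
    def test_constant_trait_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            prepare_trait(pd.Series([17.5] * 50), "bmi_ap")

    def test_age_trait_not_logged_but_standardized(self, rng):
        values = pd.Series(rng.uniform(3, 7, 500))
        tv = prepare_trait(values, "age_ar")
        assert tv.transform == "none"
        assert tv.covariates == "sex"
        assert tv.values.mean() == pytest.approx(0.0, abs=1e-10)
        assert tv.values.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_log_reduces_skewness_of_lognormal_sample(self, rng):
        raw = pd.Series(np.exp(rng.normal(0, 0.5, 10000)))
        tv = prepare_trait(raw, "bmi_ap")
        skew_before = stats.skew(raw)
        skew_after = stats.skew(tv.values)
        assert abs(skew_after) < abs(skew_before)

    def test_nonpositive_value_under_log_names_subject(self):
        values = pd.Series([1.0, 2.0, -0.5], index=["a", "b", "bad"])
        with pytest.raises(ValueError, match="bad"):
            prepare_trait(values, "pwv")

    def test_zscoring_is_idempotent(self, rng):
        values = pd.Series(rng.uniform(3, 7, 300))
        once = prepare_trait(values, "age_ar").values
        twice = prepare_trait(once, "age_ar").values
        np.testing.assert_allclose(once, twice, atol=1e-12)

    def test_missing_values_propagate(self, rng):
        values = pd.Series(rng.uniform(3, 7, 100))
        values.iloc[5] = np.nan
        tv = prepare_trait(values, "age_ar")
        assert np.isnan(tv.values.iloc[5])
        assert tv.values.notna().sum() == 99


class TestSnpAssociation:
    def test_exact_linear_phenotype(self, rng):
        n = 300
        dose = pd.Series(rng.binomial(2, 0.3, n).astype(float))
        tv = _trait_vector(0.5 * dose)
        rec = run_snp_association(tv, dose, _covars(n, rng))
        assert rec.beta == pytest.approx(0.5, abs=1e-12)
        assert rec.se < 1e-10

    def test_matches_normal_equations_oracle(self, rng):
        n = 200
        dose = pd.Series(rng.binomial(2, 0.25, n).astype(float))
        cov = _covars(n, rng)
        y = 0.1 * dose + 0.05 * cov["sex"] + rng.normal(0, 1, n)
        tv = _trait_vector(y)
        rec = run_snp_association(tv, dose, cov)
        X = np.column_stack([np.ones(n), dose, cov["sex"], cov["ga_weeks"]])
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = XtX_inv @ X.T @ y
        resid = y - X @ beta
        sigma2 = resid @ resid / (n - 4)
        assert rec.beta == pytest.approx(beta[1], abs=1e-10)
        assert rec.se == pytest.approx(np.sqrt(sigma2 * XtX_inv[1, 1]), abs=1e-10)
        assert rec.p == pytest.approx(
            2 * stats.t.sf(abs(beta[1]) / np.sqrt(sigma2 * XtX_inv[1, 1]), n - 4),
            rel=1e-10)

    def test_rebound_traits_adjust_for_sex_only(self, rng):
        n = 250
        dose = pd.Series(rng.binomial(2, 0.3, n).astype(float))
        cov = _covars(n, rng)
        y = rng.normal(0, 1, n) + 0.3 * cov["ga_weeks"]
        rec_ga = run_snp_association(_trait_vector(y, covariates="sex+ga"),
                                     dose, cov)
        rec_sex = run_snp_association(_trait_vector(y, covariates="sex"),
                                      dose, cov)
        # GA explains variance, so residual SEs must differ between the rules
        assert rec_ga.se != rec_sex.se

    def test_invariant_to_affine_covariate_recoding(self, rng):
        n = 250
        dose = pd.Series(rng.binomial(2, 0.3, n).astype(float))
        cov = _covars(n, rng)
        y = 0.1 * dose + 0.1 * cov["ga_weeks"] + rng.normal(0, 1, n)
        tv = _trait_vector(y)
        rec1 = run_snp_association(tv, dose, cov)
        cov2 = cov.copy()
        cov2["ga_weeks"] = 3.0 * cov2["ga_weeks"] + 7.0
        rec2 = run_snp_association(tv, dose, cov2)
        assert rec1.beta == pytest.approx(rec2.beta, abs=1e-10)
        assert rec1.se == pytest.approx(rec2.se, abs=1e-10)

    def test_monomorphic_snp_flagged_without_estimate(self, rng):
        n = 100
        dose = pd.Series(np.zeros(n))
        tv = _trait_vector(rng.normal(0, 1, n))
        rec = run_snp_association(tv, dose, _covars(n, rng))
        assert rec.note == "monomorphic"
        assert np.isnan(rec.beta)

    def test_scan_agrees_with_single_snp_records(self, rng):
        n = 400
        doses = pd.DataFrame(
            rng.binomial(2, 0.3, (n, 20)).astype(float),
            columns=[f"rs{i}" for i in range(20)])
        cov = _covars(n, rng)
        tv = _trait_vector(rng.normal(0, 1, n))
        scan = association_scan(tv, doses, cov)
        for snp in ("rs0", "rs7", "rs19"):
            rec = run_snp_association(tv, doses[snp], cov)
            row = scan.set_index("snp_id").loc[snp]
            assert row["beta"] == pytest.approx(rec.beta, abs=1e-10)
            assert row["se"] == pytest.approx(rec.se, abs=1e-10)
            assert row["p"] == pytest.approx(rec.p, rel=1e-8)

    def test_null_scan_type_one_error(self, rng):
        n, m = 800, 600
        doses = pd.DataFrame(
            rng.binomial(2, 0.3, (n, m)).astype(float),
            columns=[f"rs{i}" for i in range(m)])
        tv = _trait_vector(rng.normal(0, 1, n))
        scan = association_scan(tv, doses, _covars(n, rng))
        frac = (scan["p"] < 0.05).mean()
        assert 0.02 < frac < 0.09


class TestQcFilter:
    def _records(self):
        return pd.DataFrame({
            "snp_id": [f"rs{i}" for i in range(6)],
            "eaf": [0.005, 0.3, 0.3, 0.3, 0.4, 0.5],
            "info": [0.9, 0.35, 0.9, 0.9, 0.95, 1.0],
            "hwe_p": [0.5, 0.5, 1e-5, 0.5, 0.2, 0.9],
            "beta": 0.1, "se": 0.05, "p": 0.05,
        })

    def test_toy_records_filtered_per_criterion(self):
        kept, counts = qc_filter(self._records(), QCThresholds())
        assert len(kept) == 3
        assert counts == {"maf": 1, "info": 1, "hwe": 1}

    def test_vacuous_thresholds_keep_everything(self):
        thr = QCThresholds(min_maf=1e-300, min_info=1e-300, min_r2=1e-300,
                           min_hwe_p=1e-300, min_call_rate=1e-300)
        kept, _ = qc_filter(self._records(), thr)
        assert len(kept) == 6

    def test_empty_input_gives_empty_output(self):
        kept, _ = qc_filter(self._records().iloc[:0], QCThresholds())
        assert len(kept) == 0

    def test_unknown_dialect_rejected(self):
        with pytest.raises(ValueError, match="dialect"):
            qc_filter(self._records(), QCThresholds(), dialect="beagle")

    def test_mach_dialect_uses_r2_cutoff(self):
        kept, _ = qc_filter(self._records(), QCThresholds(), dialect="mach")
        # info=0.35 passes the MACH r2 > 0.3 rule
        assert "rs1" in set(kept["snp_id"])


class TestGenomicControl:
    def _null_records(self, rng, m):
        z = rng.standard_normal(m)
        return pd.DataFrame({
            "snp_id": [f"rs{i}" for i in range(m)],
            "beta": z, "se": np.ones(m),
            "p": 2 * stats.norm.sf(np.abs(z)),
        })

    def test_calibrated_null_leaves_records_unchanged(self):
        # construct chi-squares whose median is exactly the chi2(1) median
        chis = np.array([0.1, 0.2, CHI2_1_MEDIAN, 0.9, 1.5])
        df = pd.DataFrame({"beta": np.sqrt(chis), "se": 1.0,
                           "p": stats.chi2.sf(chis, 1)})
        with pytest.warns(UserWarning, match="unstable"):
            out, lam = genomic_control(df)
        assert lam == pytest.approx(1.0, abs=1e-12)
        pd.testing.assert_frame_equal(out, df)

    def test_scale_equivariance(self, rng):
        df = self._null_records(rng, 5000)
        _, lam1 = genomic_control(df)
        doubled = df.assign(beta=df["beta"] * np.sqrt(2))
        out, lam2 = genomic_control(doubled)
        assert lam2 == pytest.approx(2 * lam1, rel=1e-12)
        chi_corr = (out["beta"] / out["se"]) ** 2
        assert np.median(chi_corr) == pytest.approx(CHI2_1_MEDIAN, rel=1e-12)

    def test_null_lambda_near_one(self, rng):
        _, lam = genomic_control(self._null_records(rng, 100000))
        assert 0.97 < lam < 1.03

    def test_correction_never_decreases_p(self, rng):
        df = self._null_records(rng, 2000)
        df["beta"] *= 1.3  # inflate
        df["p"] = 2 * stats.norm.sf(np.abs(df["beta"] / df["se"]))
        out, lam = genomic_control(df)
        assert lam > 1
        assert (out["p"] >= df["p"] - 1e-15).all()

    def test_deflation_is_not_corrected(self, rng):
        df = self._null_records(rng, 2000)
        df["beta"] *= 0.5
        out, lam = genomic_control(df)
        assert lam < 1
        pd.testing.assert_frame_equal(out, df)
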
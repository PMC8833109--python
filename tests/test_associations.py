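"""Screening, OCAA association models, FDR, shrinkage, aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from omiclocks import (DataError, DiseaseSpec, apply_screening,
                       associate_ocaa_disease, associate_ocaa_risk_factor,
                       bh_fdr, enrichment_summary, hazard_doubling_years,
                       incident_table, ivw_by_clock, ivw_mean, one_sided_p,
                       screen_chronage_disease, screen_chronage_risk_factor,
                       sex_difference_test, sex_stratified_consistency,
                       shrink_beta, simulate_cohort, standardise_outcome)
from omiclocks.associations import AssociationResult, is_excluded
from tests.conftest import one_assay_config


class TestElementaryStatistics:
    def test_bh_step_up_hand_example(self):
        flags = bh_fdr([0.01, 0.02, 0.04, 0.9], q=0.10)
        assert flags.tolist() == [True, True, True, False]

    def test_bh_all_tiny_all_pass_and_empty_empty(self):
        assert bh_fdr([1e-10] * 5).all()
        assert bh_fdr([]).size == 0

    def test_shrinkage_posterior_mean(self):
        assert shrink_beta(1.0, 1.0) == pytest.approx(0.5)
        assert shrink_beta(2.0, 1e-9) == pytest.approx(2.0)
        assert abs(shrink_beta(2.0, 1e6)) < 1e-9

    def test_ivw_closed_forms(self):
        mean, se = ivw_mean([1.0, 3.0], [1.0, 2.0])
        assert mean == pytest.approx(1.4)
        assert se == pytest.approx(np.sqrt(1 / 1.25))
        mean, _ = ivw_mean([5.0, 9.0], [2.0, 2.0])
        assert mean == pytest.approx(7.0)          # equal SEs -> plain mean
        mean, _ = ivw_mean([5.0, 9.0], [1e-9, 2.0])
        assert mean == pytest.approx(5.0)          # tiny SE dominates

    def test_sex_difference_normal_quantiles(self):
        assert sex_difference_test(1.0, 1.0, 1.0, 1.0) == pytest.approx(1.0)
        d = 1.96 * np.sqrt(2.0)
        assert sex_difference_test(d, 1.0, 0.0, 1.0) == pytest.approx(
            0.05, abs=0.001)
        assert sex_difference_test(100.0, 0.1, 0.0, 0.1) < 1e-10

    def test_hazard_doubling_horizon(self):
        assert hazard_doubling_years(np.log(2) / 10) == pytest.approx(10.0)
        with pytest.raises(DataError):
            hazard_doubling_years(-0.1)


class TestRiskFactorScreening:
    def test_recovers_simulated_slope_within_two_se(self, rng):
        n = 1000
        age = rng.uniform(16, 100, n)
        sex = rng.integers(0, 2, n)
        slope = 0.02  # SD units per year
        y = slope * age + rng.normal(size=n)
        ids = pd.Index([f"I{i}" for i in range(n)])
        sd = y.std(ddof=1)
        s = screen_chronage_risk_factor(
            pd.Series(y / sd, index=ids, name="rf"),
            pd.Series(age, index=ids), pd.Series(sex, index=ids))
        assert abs(s.chron_age_beta - slope / sd) < 2 * s.se
        assert s.p_one_sided < 1e-6

    def test_null_one_sided_p_uniform(self, rng):
        ps = []
        for _ in range(200):
            n = 200
            age = rng.uniform(16, 100, n)
            ids = pd.Index([f"I{i}" for i in range(n)])
            s = screen_chronage_risk_factor(
                pd.Series(rng.normal(size=n), index=ids, name="rf"),
                pd.Series(age, index=ids),
                pd.Series(rng.integers(0, 2, n), index=ids))
            ps.append(s.p_one_sided)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_null_family_false_discovery_controlled(self, rng):
        """Mean false-discovery proportion across replicates stays near q."""
        fdps = []
        for _ in range(50):
            n = 300
            age = rng.uniform(16, 100, n)
            ids = pd.Index([f"I{i}" for i in range(n)])
            sex = pd.Series(rng.integers(0, 2, n), index=ids)
            screens = [screen_chronage_risk_factor(
                pd.Series(rng.normal(size=n), index=ids, name=f"rf{j}"),
                pd.Series(age, index=ids), sex) for j in range(8)]
            apply_screening(screens, q=0.10)
            n_pass = sum(s.fdr_pass for s in screens)
            fdps.append(n_pass / max(n_pass, 1) if n_pass else 0.0)
        assert np.mean(fdps) <= 0.15


class TestDiseaseScreening:
    def test_cox_recovers_generator_log_hr(self, large_disease_sim):
        study = large_disease_sim
        s = screen_chronage_disease(study.disease, study.cohort, "I10-I15")
        assert s.n_events > 200
        assert abs(s.chron_age_beta - 0.0492) < 2 * s.se
        # the doubling horizon implied by the fit is near 14 years
        assert 11 < hazard_doubling_years(s.chron_age_beta) < 18

    def test_too_few_events_raises(self):
        cfg = one_assay_config(seed=3, n=200)
        cfg.diseases = [DiseaseSpec("rare", baseline_rate=1e-9)]
        study = simulate_cohort(cfg)
        with pytest.raises(DataError, match="events"):
            screen_chronage_disease(study.disease, study.cohort, "rare")

    def test_eligibility_gate(self, large_disease_sim):
        study = large_disease_sim
        s = screen_chronage_disease(study.disease, study.cohort, "I10-I15")
        apply_screening([s], q=0.10)
        assert s.fdr_pass and s.eligible
        # a negative-effect screen can never be eligible
        s.chron_age_beta = -abs(s.chron_age_beta)
        apply_screening([s], q=0.10)
        assert not s.eligible


class TestOcaaAssociations:
    def test_null_ocaa_effect_small_on_risk_factor(self, rng):
        n = 2000
        age = rng.uniform(16, 100, n)
        ids = pd.Index([f"I{i}" for i in range(n)])
        y = standardise_outcome(pd.Series(
            0.02 * age + rng.normal(size=n), index=ids, name="rf"))
        r = associate_ocaa_risk_factor(
            y, pd.Series(rng.normal(0, 5, n), index=ids),
            pd.Series(age, index=ids),
            pd.Series(rng.integers(0, 2, n), index=ids),
            chron_age_beta=0.02)
        assert abs(r.beta) < 2 * r.se

    def test_constructed_outcome_rescales_to_one(self, rng):
        """outcome = a*(chronAge + OCAA) + noise -> rescaled_beta ~ 1."""
        n = 4000
        age = rng.uniform(16, 100, n)
        ocaa = rng.normal(0, 5, n)
        ids = pd.Index([f"I{i}" for i in range(n)])
        y = pd.Series(0.05 * age + 0.05 * ocaa + rng.normal(size=n),
                      index=ids, name="rf")
        y = standardise_outcome(y)
        age_s = pd.Series(age, index=ids)
        sex = pd.Series(rng.integers(0, 2, n), index=ids)
        screen = screen_chronage_risk_factor(y, age_s, sex)
        r = associate_ocaa_risk_factor(y, pd.Series(ocaa, index=ids), age_s,
                                       sex, screen.chron_age_beta)
        assert r.rescaled_beta == pytest.approx(1.0, abs=3 * r.rescaled_se)

    def test_standardised_ocaa_keeps_t_statistic(self, rng):
        n = 1500
        age = rng.uniform(16, 100, n)
        ocaa = rng.normal(0, 5, n)
        ids = pd.Index([f"I{i}" for i in range(n)])
        y = standardise_outcome(pd.Series(
            0.03 * age + 0.04 * ocaa + rng.normal(size=n), index=ids,
            name="rf"))
        age_s, sex = pd.Series(age, index=ids), pd.Series(
            rng.integers(0, 2, n), index=ids)
        raw = associate_ocaa_risk_factor(y, pd.Series(ocaa, index=ids),
                                         age_s, sex, 0.03)
        z = (ocaa - ocaa.mean()) / ocaa.std(ddof=1)
        std = associate_ocaa_risk_factor(y, pd.Series(z, index=ids), age_s,
                                         sex, 0.03)
        assert std.beta / std.se == pytest.approx(raw.beta / raw.se,
                                                  rel=1e-6)
        assert std.beta == pytest.approx(raw.beta * ocaa.std(ddof=1),
                                         rel=1e-6)

    def test_oracle_clock_recovers_hazard_ratio_ratio(self, oracle_ocaa_sim):
        """With OCAA = delta exactly, the rescaled disease effect estimates
        log_hr_delta / log_hr_age = 1."""
        study = oracle_ocaa_sim
        r = associate_ocaa_disease(study.disease, study.cohort,
                                   study.truth["delta"], "E10-E14")
        assert r.rescaled_beta == pytest.approx(1.0, abs=2 * r.rescaled_se)

    def test_attenuation_monotone_in_clock_noise(self, oracle_ocaa_sim, rng):
        study = oracle_ocaa_sim
        estimates = []
        for noise_sd in (0.0, 5.0, 12.0):
            ocaa = study.truth["delta"] + rng.normal(
                0, noise_sd, len(study.truth))
            r = associate_ocaa_disease(study.disease, study.cohort, ocaa,
                                       "E10-E14")
            estimates.append(r.rescaled_beta)
        assert estimates[0] > estimates[1] > estimates[2]

    def test_null_delta_gives_null_rescaled_effect(self, large_disease_sim):
        study = large_disease_sim  # log_hr_delta = 0
        r = associate_ocaa_disease(study.disease, study.cohort,
                                   study.truth["delta"], "I10-I15")
        assert abs(r.rescaled_beta) < 3 * r.rescaled_se

    def test_smoking_covariate_accepted(self, rng):
        n = 1500
        age = rng.uniform(16, 100, n)
        ids = pd.Index([f"I{i}" for i in range(n)])
        smoking = pd.Series(rng.integers(0, 2, n), index=ids)
        y = standardise_outcome(pd.Series(
            0.02 * age + 0.5 * smoking + rng.normal(size=n),
            index=ids, name="rf"))
        r = associate_ocaa_risk_factor(
            y, pd.Series(rng.normal(0, 5, n), index=ids),
            pd.Series(age, index=ids),
            pd.Series(rng.integers(0, 2, n), index=ids),
            chron_age_beta=0.02, smoking=smoking)
        assert np.isfinite(r.beta)


class TestExclusionsAndSummaries:
    def test_paper_style_exclusion_rules(self):
        assert is_excluded("clinomics", "bmi", "risk_factor")
        assert not is_excluded("clinomics", "E10-E14", "disease")
        assert is_excluded("nmr_metabolomics", "creatinine", "risk_factor")
        assert not is_excluded("cpg_panel", "creatinine", "risk_factor")

    def test_enrichment_counts(self):
        mk = lambda b, p: AssociationResult(
            "c", "o", "risk_factor", beta=b, se=1.0, p_one_sided=p,
            rescaled_beta=b, rescaled_se=1.0, shrunk_beta=b, n_used=10)
        res = [mk(1.0, 0.01), mk(0.5, 0.2), mk(-0.2, 0.5)]
        s = enrichment_summary(res)["risk_factor"]
        assert s["positive_fraction"] == pytest.approx(2 / 3)
        assert s["nominal_fraction"] == pytest.approx(1 / 3)

    def test_ivw_by_clock_drops_nonconverged(self):
        mk = lambda b, ok: AssociationResult(
            "c", f"o{b}", "disease", beta=b, se=0.5, p_one_sided=0.1,
            rescaled_beta=b, rescaled_se=0.5, shrunk_beta=b, n_used=10,
            n_events=8, converged=ok)
        with pytest.warns(UserWarning, match="non-converged"):
            tab = ivw_by_clock([mk(1.0, True), mk(3.0, True),
                                mk(100.0, False)])
        assert tab["ivw_rescaled_beta"].iloc[0] == pytest.approx(2.0)
        assert tab["n_outcomes"].iloc[0] == 2

    def test_one_sided_p_normal_tail(self):
        assert one_sided_p(1.96, 1.0) == pytest.approx(0.025, abs=0.001)
        assert one_sided_p(-1.0, 1.0) > 0.8


class TestSexConsistency:
    def test_strong_shared_effect_is_sign_consistent(self):
        cfg = one_assay_config(seed=77, n=6000)
        cfg.diseases = [DiseaseSpec("E10-E14", baseline_rate=6e-4,
                                    log_hr_age=0.0492, log_hr_delta=0.1)]
        study = simulate_cohort(cfg)
        ocaa = pd.DataFrame({"oracle": study.truth["delta"]})
        pooled = [associate_ocaa_disease(study.disease, study.cohort,
                                         ocaa["oracle"], "E10-E14",
                                         clock_name="oracle")]
        out = sex_stratified_consistency(study.disease, study.cohort, ocaa,
                                         pooled)
        assert out["n_candidates"] == 1
        assert out["n_assessed"] == 1
        assert out["sign_consistency"] == 1.0
        assert out["discrepant"] == []
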
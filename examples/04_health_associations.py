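"""Does clock age acceleration (OCAA) predict risk factors and disease?

Outcomes are first screened for a positive chronAge association (one-sided
BH-FDR < 10%, >5 incident cases for disease blocks); eligible outcomes are
then tested against each clock's OCAA with chronAge and sex as covariates.
Effects are rescaled to per-year-of-chronAge units - trait-by-trait for
risk factors, and by the pooled 0.0492 per-year log hazard (risk doubling
every ~14 years) for diseases - then aggregated per clock by inverse
variance weighting.
"""

import pandas as pd

from omiclocks import (POOLED_DISEASE_DIVISOR, apply_screening,
                       associate_ocaa_disease, associate_ocaa_risk_factor,
                       compute_ocaa, default_config, enrichment_summary,
                       hazard_doubling_years, ivw_by_clock, predict_age,
                       qc_pipeline, screen_chronage_disease,
                       screen_chronage_risk_factor, simulate_cohort,
                       split_cohort, standardise_outcome, train_clock)

cfg = default_config(seed=1, n_individuals=2000)
study = simulate_cohort(cfg)
cohort = study.cohort
chron_age, sex = cohort["chron_age"], cohort["sex"]

print(f"pooled chronAge divisor for disease: {POOLED_DISEASE_DIVISOR} "
      f"log HR/year -> risk doubles every "
      f"{hazard_doubling_years(POOLED_DISEASE_DIVISOR):.0f} years")

# --- screening -----------------------------------------------------------
rf_screens = [screen_chronage_risk_factor(
    standardise_outcome(study.risk_factors[c]), chron_age, sex)
    for c in study.risk_factors.columns]
apply_screening(rf_screens)
dz_screens = [screen_chronage_disease(study.disease, cohort, n)
              for n in study.disease["disease_name"].unique()]
apply_screening(dz_screens)
print("\nscreened-eligible outcomes "
      "(positive chronAge effect, FDR<10%, >5 cases):")
for s in rf_screens + dz_screens:
    tag = "eligible" if s.eligible else "dropped"
    print(f"  {s.outcome_name:12s} beta={s.chron_age_beta:+.4f} "
          f"p={s.p_one_sided:.2g} {tag}")

# --- one informative clock's OCAA ---------------------------------------
assay = study.omics[1]  # proteomics-like
matrix, _ = qc_pipeline(assay)
train_ids, test_ids = split_cohort(matrix.individual_ids, seed=1)
model = train_clock(matrix, chron_age, train_ids, test_ids, n_lambdas=50,
                    seed=1)
ocaa = compute_ocaa(predict_age(model, matrix.subset(test_ids)), chron_age)
print(f"\nclock {assay.assay_name}: test_r {model.test_r:.2f}, "
      f"OCAA SD {ocaa.std():.1f} years (test sample n={ocaa.notna().sum()})")

results = []
for s in rf_screens:
    if s.eligible:
        results.append(associate_ocaa_risk_factor(
            standardise_outcome(study.risk_factors[s.outcome_name]), ocaa,
            chron_age, sex, s.chron_age_beta, clock_name=assay.assay_name))
for s in dz_screens:
    if s.eligible:
        results.append(associate_ocaa_disease(
            study.disease, cohort, ocaa, s.outcome_name,
            clock_name=assay.assay_name))

print("\nOCAA associations (rescaled: 1 = a year of OCAA is as deleterious "
      "as a year of chronAge):")
for r in results:
    print(f"  {r.outcome_name:12s} [{r.outcome_type:11s}] "
          f"beta/yr={r.beta:+.4f} rescaled={r.rescaled_beta:+.2f} "
          f"shrunk={r.shrunk_beta:+.3f} p={r.p_one_sided:.2g}")

print("\nenrichment:", enrichment_summary(results))
print(ivw_by_clock(results).to_string(index=False))
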
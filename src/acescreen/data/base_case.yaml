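# Base-case inputs for the screening cost-utility model.
# Probabilities may be written as proportions or with an explicit '%' suffix.
# Costs are 2024 Thai baht.  Fields omitted here fall back to documented
# package defaults (see docs/methods.md for provenance of every value).

prevalence:
  mg: {value: 2.7%, cases: 3, cohort: 110}
  thyroid: {value: 0.9%, cases: 1, cohort: 110}

test_accuracy:
  achr_ab: {sensitivity: 75%, specificity: 98%}
  tft: {sensitivity: 90%, specificity: 92%}

costs:
  achr_ab_test: 1900
  tsh: 170
  ft3: 170
  ft4: 150
  chest_ct: 8200
  mri_brain_orbit: 16000
  followup_visit: 750
  visits_per_patient: 6
  annual_treatment:
    omg: 0
    hypothyroid: 0

utilities:
  early_dx_omg: 0.872
  delayed_dx_omg: 0.739
  treated_hypothyroid: 0.94
  delayed_hypothyroid: 0.94
  idiopathic_ace: 1.0
  missed_condition: 0.965
  generalized_mg: 0.739
  death: 0.0

settings:
  discount_rate_annual: 0.03
  horizon_years: 10
  cohort_size: 110
  wtp_lower: 160000
  wtp_upper: 200000
  targeted_fraction: 0.30
  psa_draws: 10000
  dsa_variation: 0.20

transitions:
  background_mortality: 0.005
  omg_to_generalized: 0.05
  incident_omg: 0.0
  incident_hypothyroid: 0.0
  symptom_triggered_detection: 0.25
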
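# Default generator calibration: seven pooled Australian / New Zealand
# early-childhood cohorts (total n = 3572).  Edge values are the published
# pooled point estimates on their reporting scale ("beta" = linear
# coefficient, "or" = odds ratio, converted to log-odds when loaded);
# per-cohort profiles carry the descriptive marginals (means, SDs,
# prevalences) the generator calibrates its intercepts to.
edges:
  - {parent: maternal_bmi, child: birth_weight, value: 0.01, scale: beta}
  - {parent: maternal_bmi, child: bf_ge6, value: 0.92, scale: or}
  - {parent: maternal_bmi, child: rwg, value: 1.00, scale: or}
  - {parent: maternal_bmi, child: bmiz_child, value: 0.03, scale: beta}
  - {parent: maternal_bmi, child: overweight, value: 1.07, scale: or}
  - {parent: birth_weight, child: bf_ge6, value: 1.28, scale: or}
  - {parent: birth_weight, child: rwg, value: 0.14, scale: or}
  - {parent: birth_weight, child: bmiz_child, value: 0.57, scale: beta}
  - {parent: birth_weight, child: overweight, value: 3.46, scale: or}
  - {parent: bf_ge6, child: rwg, value: 0.47, scale: or}
  - {parent: bf_ge6, child: bmiz_child, value: 0.04, scale: beta}
  - {parent: bf_ge6, child: overweight, value: 0.91, scale: or}
  - {parent: rwg, child: bmiz_child, value: 0.72, scale: beta}
  - {parent: rwg, child: overweight, value: 4.49, scale: or}

# Residual scales for the two Gaussian equations (kg; z-score units).
noise_sd:
  birth_weight: 0.5
  bmiz_child: 1.0

# Modest, realistic covariate effects on the linear-predictor scale
# (sex: 1 = boy; maternal_age in years; intervention: 1 = intervention arm).
# Cohort-level mean differences are absorbed by the calibrated intercepts.
covariate_effects:
  birth_weight: {sex: 0.12, maternal_age: 0.0, intervention: 0.0}
  bf_ge6: {sex: -0.10, maternal_age: 0.05, intervention: 0.0}
  rwg: {sex: 0.10, maternal_age: 0.0, intervention: 0.0, age_infancy: 0.0}
  bmiz_child: {sex: 0.0, maternal_age: 0.0, intervention: 0.0, age_child: 0.0}
  overweight: {sex: 0.0, maternal_age: 0.0, intervention: 0.0, age_child: 0.0}

cohorts:
  - cohort_id: BIS
    n: 562
    observational: true        # population-based birth cohort, no trial arm
    intervention_prop: 0.0
    maternal_age: {mean: 31.8, sd: 4.3}
    maternal_bmi: {mean: 25.2, sd: 5.1, floor: 15.0}
    tertiary_education_prop: 0.557
    male_prop: 0.537
    age_infancy: {mean: 1.1, sd: 0.1}
    age_child: {mean: 4.1, sd: 0.2}
    birth_weight_mean: 3.5
    bmiz_mean: 0.2
    prevalence: {bf_ge6: 0.658, rwg: 0.256, overweight: 0.114}
  - cohort_id: HB
    n: 275
    observational: false
    intervention_prop: 0.505
    maternal_age: {mean: 27.4, sd: 5.3}
    maternal_bmi: {mean: 25.3, sd: 5.4, floor: 15.0}
    tertiary_education_prop: 0.675
    male_prop: 0.531
    age_infancy: {mean: 1.0, sd: 0.0}
    age_child: {mean: 5.0, sd: 0.1}
    birth_weight_mean: 3.4
    bmiz_mean: 0.6
    prevalence: {bf_ge6: 0.440, rwg: 0.360, overweight: 0.215}
  - cohort_id: InFANT
    n: 352
    observational: false
    intervention_prop: 0.507
    maternal_age: {mean: 32.5, sd: 4.1}
    maternal_bmi: {mean: 24.1, sd: 5.2, floor: 15.0}
    tertiary_education_prop: 0.597
    male_prop: 0.523
    age_infancy: {mean: 0.8, sd: 0.1}
    age_child: {mean: 5.1, sd: 0.2}
    birth_weight_mean: 3.3
    bmiz_mean: 0.5
    prevalence: {bf_ge6: 0.668, rwg: 0.290, overweight: 0.159}
  - cohort_id: InFANT Extend
    n: 243
    observational: false
    intervention_prop: 0.508
    maternal_age: {mean: 32.5, sd: 4.2}
    maternal_bmi: {mean: 24.2, sd: 4.6, floor: 15.0}
    tertiary_education_prop: 0.613
    male_prop: 0.502
    age_infancy: {mean: 0.8, sd: 0.2}
    age_child: {mean: 3.2, sd: 0.1}
    birth_weight_mean: 3.3
    bmiz_mean: 0.8
    prevalence: {bf_ge6: 0.757, rwg: 0.309, overweight: 0.144}
  - cohort_id: LIMIT
    n: 1230
    observational: false
    intervention_prop: 0.502
    maternal_age: {mean: 30.0, sd: 5.3}
    # pregnancy trial restricted to women with overweight/obesity:
    # truncation floored at the overweight bound
    maternal_bmi: {mean: 32.2, sd: 5.8, floor: 25.0}
    tertiary_education_prop: null
    male_prop: 0.496
    age_infancy: {mean: 0.6, sd: 0.2}
    age_child: {mean: 3.3, sd: 0.5}
    birth_weight_mean: 3.5
    bmiz_mean: 0.8
    prevalence: {bf_ge6: 0.556, rwg: 0.232, overweight: 0.224}
  - cohort_id: Nourish
    n: 395
    observational: false
    intervention_prop: 0.480
    maternal_age: {mean: 31.9, sd: 5.0}
    maternal_bmi: {mean: 25.7, sd: 5.2, floor: 15.0}
    tertiary_education_prop: 0.699
    male_prop: 0.481
    age_infancy: {mean: 1.1, sd: 0.1}
    age_child: {mean: 5.0, sd: 0.0}
    birth_weight_mean: 3.5
    bmiz_mean: 0.4
    prevalence: {bf_ge6: 0.709, rwg: 0.291, overweight: 0.122}
  - cohort_id: POI
    n: 515
    observational: false
    intervention_prop: 0.488
    maternal_age: {mean: 32.7, sd: 4.6}
    maternal_bmi: {mean: 25.1, sd: 4.9, floor: 15.0}
    tertiary_education_prop: 0.682
    male_prop: 0.518
    age_infancy: {mean: 1.0, sd: 0.0}
    age_child: {mean: 5.0, sd: 0.0}
    birth_weight_mean: 3.6
    bmiz_mean: 0.5
    prevalence: {bf_ge6: 0.750, rwg: 0.212, overweight: 0.153}
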
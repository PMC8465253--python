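# Clinical study arms used for model construction and evaluation.
#
# Values (subjects, dose, formulation, age, weight, female proportion,
# source) are shipped exactly as compiled from the source studies,
# including internal inconsistencies, which are flagged via `anomaly`
# and surfaced as warnings on load rather than silently corrected.
#
# duration_h is this package's estimate of each study's sampling horizon:
# the source durations are not tabulated, and the compiled CL column is
# dose/AUC0-t by construction, so the horizon was chosen per arm to be
# consistent with how complete each printed AUC0-t is relative to
# dose/CL (short horizons where dose/AUC0-t far exceeds the plausible
# plasma clearance, long ones where it approaches it).
arms:
  # ------------------------------------------------------------------ IV
  iv_2mg:
    route: iv_bolus
    formulation: solution
    reference: B46
    n_subjects_observed: 9
    dose_mg: 2
    age: {min: 20, max: 30}
    weight: {min: 58, max: 80}
    female_proportion: 0.0
    duration_h: 4
  iv_5mg_a:
    route: iv_bolus
    formulation: solution
    reference: B47
    n_subjects_observed: 8
    dose_mg: 5
    age: {mean: 28.3}
    female_proportion: 0.33
    duration_h: 4
  iv_5mg_b:
    route: iv_bolus
    formulation: solution
    reference: B48
    n_subjects_observed: 24
    dose_mg: 5
    age: {min: 18, max: 45}
    weight: {mean: 71.8}
    female_proportion: 0.2
    duration_h: 48
  iv_7p5mg:
    route: iv_bolus
    formulation: solution
    reference: B49
    n_subjects_observed: 20
    dose_mg: 7.5
    age: {mean: 28.8}
    weight: {mean: 72.6}
    female_proportion: 0.0
    duration_h: 24
  iv_1mg:
    route: iv_bolus
    formulation: solution
    reference: B15
    n_subjects_observed: 9
    dose_mg: 1
    age: {min: 18, max: 25}
    weight: {min: 58, max: 70}
    female_proportion: 0.33
    duration_h: 72
    anomaly: >-
      compiled dose prints 1 mg while the matching concentration profile
      and PK table are for a 10 mg IV dose; shipped as printed.
  iv_10mg:
    route: iv_bolus
    formulation: solution
    reference: B50
    n_subjects_observed: 1
    dose_mg: 10
    age: {min: 26, max: 37}
    weight: {min: 60, max: 85}
    female_proportion: 0.2
    duration_h: 96
    anomaly: >-
      compiled subject count prints 1 with a female proportion of 0.2;
      shipped as printed.
  # ---------------------------------------------------------------- oral
  oral_2mg:
    route: oral
    reference: B51
    n_subjects_observed: 11
    dose_mg: 2
    age: {min: 19, max: 35}
    female_proportion: 0.27
    duration_h: 24
  oral_5mg:
    route: oral
    reference: B51
    n_subjects_observed: 11
    dose_mg: 5
    age: {min: 19, max: 35}
    female_proportion: 0.27
    duration_h: 24
  oral_10mg_tablets:
    route: oral
    formulation: tablet
    reference: B52
    n_subjects_observed: 48
    dose_mg: 10
    age: {min: 18, max: 44}
    weight: {min: 59.1, max: 95}
    female_proportion: 0.0
    duration_h: 12
  oral_10mg:
    route: oral
    reference: B51
    n_subjects_observed: 11
    dose_mg: 10
    age: {min: 19, max: 35}
    female_proportion: 0.27
    duration_h: 24
  oral_10mg_tablet:
    route: oral
    formulation: tablet
    reference: B15
    n_subjects_observed: 9
    dose_mg: 10
    age: {min: 18, max: 25}
    weight: {min: 58, max: 70}
    female_proportion: 0.33
    duration_h: 72
  # ----------------------------------------------------------- intranasal
  intranasal_2mg:
    route: intranasal
    formulation: solution
    reference: B46
    n_subjects_observed: 9
    dose_mg: 2
    age: {min: 20, max: 30}
    weight: {min: 58, max: 80}
    female_proportion: 0.0
    duration_h: 4
  intranasal_5mg_supersaturated:
    route: intranasal
    formulation: supersaturated_solution
    reference: B47
    n_subjects_observed: 8
    dose_mg: 5
    age: {mean: 28.3}
    female_proportion: 0.33
    duration_h: 4
  intranasal_10mg_solution:
    route: intranasal
    formulation: solution
    reference: B48
    n_subjects_observed: 24
    dose_mg: 10
    age: {min: 18, max: 45}
    weight: {mean: 71.8}
    female_proportion: 0.2
    duration_h: 24
  intranasal_10mg_suspension:
    route: intranasal
    formulation: suspension
    reference: B48
    n_subjects_observed: 24
    dose_mg: 10
    age: {min: 18, max: 45}
    weight: {mean: 71.8}
    female_proportion: 0.2
    duration_h: 24
  intranasal_10mg_supersaturated:
    route: intranasal
    formulation: supersaturated_solution
    reference: B47
    n_subjects_observed: 8
    dose_mg: 10
    age: {mean: 28.3}
    female_proportion: 0.33
    duration_h: 4
  intranasal_10mg:
    route: intranasal
    formulation: solution
    reference: B50
    n_subjects_observed: 1
    dose_mg: 10
    age: {min: 26, max: 37}
    weight: {min: 60, max: 85}
    female_proportion: 0.2
    duration_h: 96
    anomaly: >-
      compiled subject count prints 1 with a female proportion of 0.2;
      shipped as printed.
  # --------------------------------------------------------------- rectal
  rectal_10mg_solution:
    route: rectal
    formulation: solution
    reference: B15
    n_subjects_observed: 9
    dose_mg: 10
    age: {min: 18, max: 25}
    weight: {min: 58, max: 70}
    female_proportion: 0.33
    duration_h: 24
  rectal_10mg_suppository:
    route: rectal
    formulation: suppository
    reference: B15
    n_subjects_observed: 9
    dose_mg: 10
    age: {min: 18, max: 25}
    weight: {min: 58, max: 70}
    female_proportion: 0.33
    duration_h: 24
  rectal_15mg_gel:
    route: rectal
    formulation: gel
    reference: B49
    n_subjects_observed: 20
    dose_mg: 15
    age: {mean: 28.8}
    weight: {mean: 173.9}
    female_proportion: 0.0
    duration_h: 8
    anomaly: >-
      compiled mean body weight prints 173.9 kg for the same cohort that
      weighs 72.6 kg in its IV arm; shipped as printed.
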
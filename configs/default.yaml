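# Reference configuration: a four-level cardiovascular-prevention trial.
# 20 hospitals (independent sampling units), 8 clinics per hospital,
# 6 providers per clinic, 6 participants per provider; 8 outcomes.
design:
  n_hospitals: 20
  n_clinics: 8
  n_providers: 6
  n_participants: 6
  randomization_level: hospital
  subgroups:
    rural: 10
    urban: 10
variance:
  icc_provider: 0.05
  icc_clinic: 0.01
  icc_hospital: 0.01
  sigma2: 1.0
  n_outcomes: 8
  outcome_covariance: identity   # or an explicit m x m matrix
  composite_weights: equal       # or an explicit length-m vector summing to 1
effect:
  affected_outcome: 1            # 1-based index; the intervention shifts only this outcome
alpha: 0.05
grid:
  delta_max: 1.0                 # 1.0 = one SD of a single outcome
  n_points: 100
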
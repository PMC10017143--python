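# Demonstration run: synthetic cohort with 3 planted oblique factors per
# period, analysed with the default thresholds (salience 0.30, >=3 drugs,
# four 5-year windows, parallel analysis at the 95th percentile).
simulate:
  n_patients: 3000
  truth:
    n_factors: 3
    meds_per_factor: 10
    salient: 0.8
    phi_offdiag: 0.3
    marginal_prevalence: 0.15
windows: [[0, 5], [5, 10], [10, 15], [15, 20]]
coding: binary
min_support: 10
correlation_method: pearson
extraction: minres
rotation: oblimin
n_factors: auto
pa_n_sims: 100
pa_percentile: 95
salience_threshold: 0.30
min_drugs: 3
min_meds: 3
top_k_diseases: 8
decimals: 2
seed: 11
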
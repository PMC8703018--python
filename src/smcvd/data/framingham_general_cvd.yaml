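# Default 10-year general-CVD risk function (sex-specific Cox survival form).
# Coefficients are the published general cardiovascular risk profile for use
# in primary care (office-based, lipid model): log-transformed age, total
# cholesterol, HDL and systolic BP (split by antihypertensive treatment),
# with smoking and diabetes as binary terms. Lipid factors are taken in
# mg/dL (the scale the coefficients were estimated on); clinical tables in
# mmol/L are converted internally. `mean_sum` is the published aggregate
# sum(beta_i * xbar_i) for each sex.
female:
  s0: 0.95012
  mean_sum: 26.1931
  terms:
    - {name: log_age,            factor: age,             beta: 2.32888, log: true}
    - {name: log_total_chol,     factor: total_chol_mgdl, beta: 1.20904, log: true}
    - {name: log_hdl,            factor: hdl_mgdl,        beta: -0.70833, log: true}
    - {name: log_sbp_untreated,  factor: sbp,             beta: 2.76157, log: true, when: "!bp_treated"}
    - {name: log_sbp_treated,    factor: sbp,             beta: 2.82263, log: true, when: "bp_treated"}
    - {name: smoker,             factor: smoker,          beta: 0.52873}
    - {name: diabetic,           factor: diabetic,        beta: 0.69154}
male:
  s0: 0.88936
  mean_sum: 23.9802
  terms:
    - {name: log_age,            factor: age,             beta: 3.06117, log: true}
    - {name: log_total_chol,     factor: total_chol_mgdl, beta: 1.12370, log: true}
    - {name: log_hdl,            factor: hdl_mgdl,        beta: -0.93263, log: true}
    - {name: log_sbp_untreated,  factor: sbp,             beta: 1.93303, log: true, when: "!bp_treated"}
    - {name: log_sbp_treated,    factor: sbp,             beta: 1.99881, log: true, when: "bp_treated"}
    - {name: smoker,             factor: smoker,          beta: 0.65451}
    - {name: diabetic,           factor: diabetic,        beta: 0.57367}
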
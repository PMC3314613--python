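{
 "sex": "female",
 "coefficients": {
  "age": 0.33766,
  "age_sq": -0.00268,
  "tc:<160": -0.26138,
  "tc:200-239": 0.20771,
  "tc:240-279": 0.24385,
  "tc:>=280": 0.53513,
  "hdl:<35": 0.84312,
  "hdl:35-44": 0.37796,
  "hdl:45-49": 0.19785,
  "hdl:>=60": -0.42951,
  "bp:optimal": -0.53363,
  "bp:high_normal": -0.06773,
  "bp:stage1": 0.26288,
  "bp:stage2_4": 0.46573,
  "diabetes": 0.59626,
  "smoking:current": 0.29246
 },
 "reference_means": {
  "age": 49.1,
  "age_sq": 2554.81,
  "tc:<160": 0.08,
  "tc:200-239": 0.33,
  "tc:240-279": 0.2,
  "tc:>=280": 0.09,
  "hdl:<35": 0.05,
  "hdl:35-44": 0.15,
  "hdl:45-49": 0.15,
  "hdl:>=60": 0.32,
  "bp:optimal": 0.23,
  "bp:high_normal": 0.2,
  "bp:stage1": 0.2,
  "bp:stage2_4": 0.11,
  "diabetes": 0.04,
  "smoking:current": 0.38
 },
 "baseline_survival": {"value": 0.96246, "horizon": 10.0, "method": "cox_at_means"},
 "provenance": "wilson",
 "notes": "Coefficients and 10-year baseline survival are the published women's categorical CHD equation values. Reference means are a SYNTHETIC approximation of the Framingham 30-74 risk-factor distribution, editable; supply exact means where required."
}
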
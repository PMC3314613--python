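{
 "sex": "male",
 "coefficients": {
  "age": 0.04826,
  "tc:<160": -0.65945,
  "tc:200-239": 0.17692,
  "tc:240-279": 0.50539,
  "tc:>=280": 0.65713,
  "hdl:<35": 0.49744,
  "hdl:35-44": 0.2431,
  "hdl:50-59": -0.05107,
  "hdl:>=60": -0.4866,
  "bp:optimal": -0.00226,
  "bp:high_normal": 0.2832,
  "bp:stage1": 0.52168,
  "bp:stage2_4": 0.61859,
  "diabetes": 0.42839,
  "smoking:current": 0.52337
 },
 "reference_means": {
  "age": 48.6,
  "tc:<160": 0.08,
  "tc:200-239": 0.33,
  "tc:240-279": 0.17,
  "tc:>=280": 0.07,
  "hdl:<35": 0.19,
  "hdl:35-44": 0.36,
  "hdl:50-59": 0.2,
  "hdl:>=60": 0.12,
  "bp:optimal": 0.19,
  "bp:high_normal": 0.22,
  "bp:stage1": 0.22,
  "bp:stage2_4": 0.12,
  "diabetes": 0.05,
  "smoking:current": 0.4
 },
 "baseline_survival": {"value": 0.90015, "horizon": 10.0, "method": "cox_at_means"},
 "provenance": "wilson",
 "notes": "Coefficients and 10-year baseline survival are the published men's categorical CHD equation values (reference categories: TC 160-199, HDL 45-49, BP normal, never/former smoking). Reference means are a SYNTHETIC approximation of the Framingham 30-74 risk-factor distribution, editable; supply exact means where required."
}
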
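{
 "TA": {
  "F_max": 617,
  "length_scale": 0.193,
  "K_sh": 2.97,
  "lambda_ref": 0.061
 },
 "SOL": {
  "F_max": 3858,
  "length_scale": 0.253,
  "K_sh": 3.31,
  "lambda_ref": 0.051
 },
 "GAS": {
  "F_max": 2278,
  "length_scale": 0.385,
  "K_sh": 3.81,
  "lambda_ref": 0.051
 },
 "VAS": {
  "F_max": 4827,
  "length_scale": 0.171,
  "K_sh": 2.86,
  "lambda_ref": 0.079
 },
 "BFSH": {
  "F_max": 398,
  "length_scale": 0.116,
  "K_sh": 2.48,
  "lambda_ref": 0.055
 },
 "RF": {
  "F_max": 621,
  "length_scale": 0.371,
  "K_sh": 3.03,
  "lambda_ref": 0.054
 },
 "HAM": {
  "F_max": 1232,
  "length_scale": 0.387,
  "K_sh": 2.67,
  "lambda_ref": 0.073
 },
 "ILL": {
  "F_max": 1079,
  "length_scale": 0.107,
  "K_sh": 3.15,
  "lambda_ref": 0.059
 },
 "GMAX": {
  "F_max": 1035,
  "length_scale": 0.11,
  "K_sh": 3.35,
  "lambda_ref": 0.056
 },
 "GMED": {
  "F_max": 1508,
  "length_scale": 0.053,
  "K_sh": 3.14,
  "lambda_ref": 0.056
 },
 "ADDL": {
  "F_max": 628,
  "length_scale": 0.103,
  "K_sh": 3.8,
  "lambda_ref": 0.05
 },
 "ADDM": {
  "F_max": 1054,
  "length_scale": 0.127,
  "K_sh": 3.61,
  "lambda_ref": 0.053
 },
 "HFL": {
  "K_HFL": 319,
  "theta0_HFL": 0.006
 }
}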
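{
 "TA": {
  "F_max": 874,
  "length_scale": 0.192,
  "K_sh": 2.33,
  "lambda_ref": 0.057
 },
 "SOL": {
  "F_max": 4632,
  "length_scale": 0.244,
  "K_sh": 2.98,
  "lambda_ref": 0.08
 },
 "GAS": {
  "F_max": 1819,
  "length_scale": 0.369,
  "K_sh": 2.93,
  "lambda_ref": 0.053
 },
 "VAS": {
  "F_max": 3229,
  "length_scale": 0.162,
  "K_sh": 2.73,
  "lambda_ref": 0.056
 },
 "BFSH": {
  "F_max": 289,
  "length_scale": 0.11,
  "K_sh": 2.4,
  "lambda_ref": 0.058
 },
 "RF": {
  "F_max": 888,
  "length_scale": 0.353,
  "K_sh": 2.22,
  "lambda_ref": 0.06
 },
 "HAM": {
  "F_max": 1189,
  "length_scale": 0.343,
  "K_sh": 2.11,
  "lambda_ref": 0.051
 },
 "ILL": {
  "F_max": 737,
  "length_scale": 0.119,
  "K_sh": 2.6,
  "lambda_ref": 0.061
 },
 "GMAX": {
  "F_max": 1452,
  "length_scale": 0.114,
  "K_sh": 2.86,
  "lambda_ref": 0.06
 },
 "GMED": {
  "F_max": 1311,
  "length_scale": 0.057,
  "K_sh": 2.67,
  "lambda_ref": 0.051
 },
 "ADDL": {
  "F_max": 353,
  "length_scale": 0.115,
  "K_sh": 2.0,
  "lambda_ref": 0.06
 },
 "ADDM": {
  "F_max": 874,
  "length_scale": 0.109,
  "K_sh": 2.59,
  "lambda_ref": 0.053
 },
 "HFL": {
  "K_HFL": 142,
  "theta0_HFL": -0.023
 }
}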
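{
 "TA": {
  "F_max": 523,
  "length_scale": 0.21,
  "K_sh": 2.73,
  "lambda_ref": 0.045
 },
 "SOL": {
  "F_max": 4219,
  "length_scale": 0.266,
  "K_sh": 2.51,
  "lambda_ref": 0.064
 },
 "GAS": {
  "F_max": 1816,
  "length_scale": 0.411,
  "K_sh": 2.86,
  "lambda_ref": 0.051
 },
 "VAS": {
  "F_max": 8141,
  "length_scale": 0.177,
  "K_sh": 3.03,
  "lambda_ref": 0.052
 },
 "BFSH": {
  "F_max": 404,
  "length_scale": 0.147,
  "K_sh": 2.85,
  "lambda_ref": 0.063
 },
 "RF": {
  "F_max": 1293,
  "length_scale": 0.381,
  "K_sh": 3.05,
  "lambda_ref": 0.059
 },
 "HAM": {
  "F_max": 1694,
  "length_scale": 0.385,
  "K_sh": 2.9,
  "lambda_ref": 0.058
 },
 "ILL": {
  "F_max": 991,
  "length_scale": 0.118,
  "K_sh": 2.46,
  "lambda_ref": 0.057
 },
 "GMAX": {
  "F_max": 1074,
  "length_scale": 0.125,
  "K_sh": 3.02,
  "lambda_ref": 0.056
 },
 "GMED": {
  "F_max": 1376,
  "length_scale": 0.052,
  "K_sh": 3.05,
  "lambda_ref": 0.056
 },
 "ADDL": {
  "F_max": 447,
  "length_scale": 0.105,
  "K_sh": 2.99,
  "lambda_ref": 0.057
 },
 "ADDM": {
  "F_max": 851,
  "length_scale": 0.131,
  "K_sh": 2.8,
  "lambda_ref": 0.055
 },
 "HFL": {
  "K_HFL": 567,
  "theta0_HFL": -0.05
 }
}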
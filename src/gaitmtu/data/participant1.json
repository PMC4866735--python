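{
 "TA": {
  "F_max": 477,
  "length_scale": 0.214,
  "K_sh": 2.19,
  "lambda_ref": 0.04
 },
 "SOL": {
  "F_max": 3974,
  "length_scale": 0.282,
  "K_sh": 2.9,
  "lambda_ref": 0.061
 },
 "GAS": {
  "F_max": 2075,
  "length_scale": 0.438,
  "K_sh": 2.49,
  "lambda_ref": 0.047
 },
 "VAS": {
  "F_max": 3864,
  "length_scale": 0.192,
  "K_sh": 2.0,
  "lambda_ref": 0.055
 },
 "BFSH": {
  "F_max": 317,
  "length_scale": 0.156,
  "K_sh": 2.15,
  "lambda_ref": 0.052
 },
 "RF": {
  "F_max": 681,
  "length_scale": 0.408,
  "K_sh": 2.93,
  "lambda_ref": 0.067
 },
 "HAM": {
  "F_max": 1503,
  "length_scale": 0.41,
  "K_sh": 2.3,
  "lambda_ref": 0.067
 },
 "ILL": {
  "F_max": 713,
  "length_scale": 0.103,
  "K_sh": 2.16,
  "lambda_ref": 0.067
 },
 "GMAX": {
  "F_max": 1405,
  "length_scale": 0.109,
  "K_sh": 2.63,
  "lambda_ref": 0.07
 },
 "GMED": {
  "F_max": 1266,
  "length_scale": 0.054,
  "K_sh": 2.79,
  "lambda_ref": 0.051
 },
 "ADDL": {
  "F_max": 403,
  "length_scale": 0.119,
  "K_sh": 2.19,
  "lambda_ref": 0.048
 },
 "ADDM": {
  "F_max": 805,
  "length_scale": 0.138,
  "K_sh": 2.28,
  "lambda_ref": 0.069
 },
 "HFL": {
  "K_HFL": 193,
  "theta0_HFL": 0.04
 }
}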
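{
 "TA": {
  "F_max": 497,
  "length_scale": 0.191,
  "K_sh": 2.45,
  "lambda_ref": 0.069
 },
 "SOL": {
  "F_max": 1992,
  "length_scale": 0.255,
  "K_sh": 2.76,
  "lambda_ref": 0.048
 },
 "GAS": {
  "F_max": 1616,
  "length_scale": 0.382,
  "K_sh": 2.93,
  "lambda_ref": 0.047
 },
 "VAS": {
  "F_max": 4472,
  "length_scale": 0.167,
  "K_sh": 2.61,
  "lambda_ref": 0.061
 },
 "BFSH": {
  "F_max": 358,
  "length_scale": 0.133,
  "K_sh": 2.6,
  "lambda_ref": 0.067
 },
 "RF": {
  "F_max": 511,
  "length_scale": 0.369,
  "K_sh": 2.76,
  "lambda_ref": 0.071
 },
 "HAM": {
  "F_max": 1177,
  "length_scale": 0.386,
  "K_sh": 2.46,
  "lambda_ref": 0.06
 },
 "ILL": {
  "F_max": 560,
  "length_scale": 0.105,
  "K_sh": 2.3,
  "lambda_ref": 0.047
 },
 "GMAX": {
  "F_max": 973,
  "length_scale": 0.115,
  "K_sh": 2.33,
  "lambda_ref": 0.048
 },
 "GMED": {
  "F_max": 1011,
  "length_scale": 0.058,
  "K_sh": 2.45,
  "lambda_ref": 0.049
 },
 "ADDL": {
  "F_max": 337,
  "length_scale": 0.097,
  "K_sh": 2.67,
  "lambda_ref": 0.042
 },
 "ADDM": {
  "F_max": 758,
  "length_scale": 0.126,
  "K_sh": 2.43,
  "lambda_ref": 0.044
 },
 "HFL": {
  "K_HFL": 128,
  "theta0_HFL": 0.045
 }
}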
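{
  "mantel": {
    "r": "number",
    "p": "number",
    "n_permutations": "integer"
  },
  "pic_grid": {
    "r": "array",
    "p": "array",
    "df": "integer",
    "null_min": "number",
    "null_max": "number",
    "null_central95": "array"
  },
  "pls": {
    "r_pls": "number",
    "p": "number"
  },
  "overall_rate_correlation": {
    "r": "number",
    "p": "number",
    "df": "integer"
  },
  "windowed_rate_correlation": {
    "windows": "array"
  }
}
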
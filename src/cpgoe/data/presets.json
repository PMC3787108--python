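{
  "hsjostedti": {
    "species": "Hodotermopsis sjostedti",
    "mixture": {"w1": 0.84, "mu1": 0.39, "sd1": 0.14, "mu2": 0.81, "sd2": 0.14}
  },
  "rsperatus": {
    "species": "Reticulitermes speratus",
    "mixture": {"w1": 0.81, "mu1": 0.41, "sd1": 0.15, "mu2": 0.82, "sd2": 0.15}
  },
  "ntakasagoensis": {
    "species": "Nasutitermes takasagoensis",
    "mixture": {"w1": 0.81, "mu1": 0.44, "sd1": 0.17, "mu2": 0.83, "sd2": 0.17}
  }
}
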
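{
  "version": "default-1",
  "psa_low": 10.0,
  "psa_high": 20.0,
  "gg_high": 4,
  "gg_very_high": 5
}
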
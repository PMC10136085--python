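{
  "Cmax": 1e4,
  "kt": 1e-4,
  "kbnd": 1e-3,
  "kubnd": 0.1,
  "complementarity": {
    "q": 8e-3,
    "qk1": 8e-3,
    "qk2": 8e-3,
    "eta": 1.0
  },
  "kleak": 0.0,
  "clamp_auxiliaries": false
}
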
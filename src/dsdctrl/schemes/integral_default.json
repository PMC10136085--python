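{
  "Cmax": 1e4,
  "kt": 1e-4,
  "kbnd": 1e-3,
  "kubnd": 0.1,
  "complementarity": {
    "a": 2.5e-3,
    "b": 1e-3,
    "ki": 5e-2,
    "eta": 0.25
  },
  "kleak": 0.0,
  "clamp_auxiliaries": false
}
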
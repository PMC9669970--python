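# Two-integrator race readout: alpha1 = 8 versus alpha2 = 3, p0 = 0.3.
model: race
protocol:
  alpha: 8.0
  epochs: [[100.0, 1000.0]]
seed: 1
duration: 1000.0
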
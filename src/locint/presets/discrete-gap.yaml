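# Discrete integrator, two stimulus epochs separated by a 500-ms gap.
model: discrete
protocol:
  epochs: [[100.0, 300.0], [800.0, 1000.0]]
seed: 1
duration: 1100.0
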
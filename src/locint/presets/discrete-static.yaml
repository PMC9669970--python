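# Control: depressing synapses replaced by static ones (no propagation).
model: discrete
protocol:
  epochs: [[100.0, 300.0], [800.0, 1000.0]]
seed: 1
duration: 1100.0
overrides: {}
# pass --variant static_synapses on the command line
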
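# Single-integrator recurrent readout for ramping/stepping analyses.
model: single_readout
protocol:
  alpha: 8.0
  epochs: [[100.0, 600.0]]
seed: 1
duration: 600.0
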
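# Rate-model fixed-point scan over the external input E at r = 1.
model: rate
seed: 1
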
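# Two-task regime comparison: flexible gate/weight timescales and unit block
# length; the forgetful control is derived by setting tau_c = tau_w and
# removing the gate regularizers.
model:
  P: 2
  din: 32
  dout: 8
  tau_w: 1.3
  tau_c: 0.03
  lambda_norm: 1.0
  lambda_nonneg: 1.0
  norm_order: 1
  gate_granularity: scalar
  sigma: 0.01
curriculum:
  M: 2
  block_length: 1.0
  n_blocks: 24
  sampling_mode: expectation
integration:
  record_every: 10
init_seed: 0
data_seed: 0
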
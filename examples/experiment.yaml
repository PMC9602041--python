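# Miniature sweep: both STDP modes, two damage levels, beta+gamma bands.
network:
  n_total: 200
  n_exc: 160
  n_inh: 40
  m_out: 50
plasticity:
  a2_plus: 0.1
  a2_minus: 0.066
  a3_minus: 0.031
ordinal:
  dim: 3
  lag: 1
modes: [pairwise, mixed]
damage_levels: [0, 60]
bands: [beta, gamma]
duration: 20000
n_windows: 5
settle_ms: 14000
sources: [lfp]
seeds:
  topology: 100
  damage: 200
  drive: 300
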
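# Example epighost experiment configuration.
# CLI flags override these values; unknown keys are rejected.

protocol:
  matrix_size: 128        # image matrix N (even)
  fov_mm: 175.0
  echo_spacing_ms: 1.26   # one readout lobe per echo spacing
  dwell_us: 5.0
  gmax_mT_per_m: 40.0
  smax_T_per_m_per_s: 48.0
  ramp_sampling: true     # false = flat-top-only ADC window
  grappa_factor: 1
  acs_lines: 24
  train_polarity: 1       # +1 or -1
  te_ms: null             # null = minimum feasible TE

imperfections:
  eddy:                   # short-term eddy modes
    - {a: 0.003, tau_us: 70.0}
    - {a: 0.002, tau_us: 300.0}
  resonance:              # gradient-shim inductive coupling
    f0_hz: 1100.0
    width_hz: 150.0
    coupling: 0.15
    enabled: true         # false = third-order shim disconnected
  delay_us: 0.0           # global gradient timing delay

seed: 20250402
out_dir: epighost_out
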
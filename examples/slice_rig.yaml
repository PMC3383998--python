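controllers:
  Slow0:
    line: Slow0
    mode: valvebits
    n_channels: 8
    volts_per_channel: 1.0
    valves_per_channel: 1
    port: Port1
    bit_base: 0
    valve_switch_time_ms: 100.0
    binary4_convention: 8ch
    flush_duration_s: 10.0
    amplitude_is_volts: false
transport:
  Slow0:
    segments:
    - length_cm: 30.0
      inner_diameter_mm: 0.8
      role: reservoir_to_junction
    - length_cm: 9.0
      inner_diameter_mm: 0.8
      role: junction_to_manifold
    flow_rate_ml_min: 2.0
    chamber_volume_ml: 1.0
    system: standard
sweep_defs:
  P0sweep:
    name: P0sweep
    duration_ms: 200.0
    sample_rate_hz: 10000.0
    s0_train:
      onset_ms: 10.0
      pulse_count: 1
      interval_ms: 10.0
      pulse_width_ms: 0.1
    s1_train: null
    ic0_steps: []
    ic1_epochs: null
  T0sweep:
    name: T0sweep
    duration_ms: 1200.0
    sample_rate_hz: 10000.0
    s0_train:
      onset_ms: 10.0
      pulse_count: 100
      interval_ms: 10.0
      pulse_width_ms: 0.1
    s1_train: null
    ic0_steps: []
    ic1_epochs: null
ic1_line: Fast0
inter_sweep_interval_s: 30.0
slow_latency_jitter_ms: 0.0
channel_solution_um: {}
biology:
  kind: slice
  baseline_slope: -0.15
  ltp_factor: 1.5
  inhibitor_channels:
  - 2
  inhibitor_block_threshold: 0.5
  noise_sd: 0.0
  rng_seed: 0
  train_pulse_threshold: 10
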
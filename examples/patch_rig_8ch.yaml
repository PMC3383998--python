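controllers:
  Fast0:
    line: Fast0
    mode: analog
    n_channels: 8
    volts_per_channel: 1.0
    valves_per_channel: 1
    port: Port1
    bit_base: 0
    valve_switch_time_ms: 4.0
    binary4_convention: 8ch
    flush_duration_s: 10.0
    amplitude_is_volts: false
transport: {}
sweep_defs:
  P0sweep:
    name: P0sweep
    duration_ms: 3000.0
    sample_rate_hz: 2000.0
    s0_train: null
    s1_train: null
    ic0_steps: []
    ic1_epochs:
    - duration_ms: 1000.0
      amplitude: -1.0
    - duration_ms: 1000.0
      amplitude: 5.0
    - duration_ms: 1000.0
      amplitude: -1.0
  P1sweep:
    name: P1sweep
    duration_ms: 3000.0
    sample_rate_hz: 2000.0
    s0_train: null
    s1_train: null
    ic0_steps: []
    ic1_epochs:
    - duration_ms: 1000.0
      amplitude: -1.0
    - duration_ms: 1000.0
      amplitude: 6.0
    - duration_ms: 1000.0
      amplitude: -1.0
  T0sweep:
    name: T0sweep
    duration_ms: 3000.0
    sample_rate_hz: 2000.0
    s0_train: null
    s1_train: null
    ic0_steps: []
    ic1_epochs:
    - duration_ms: 1000.0
      amplitude: -1.0
    - duration_ms: 1000.0
      amplitude: 7.0
    - duration_ms: 1000.0
      amplitude: -1.0
  T1sweep:
    name: T1sweep
    duration_ms: 3000.0
    sample_rate_hz: 2000.0
    s0_train: null
    s1_train: null
    ic0_steps: []
    ic1_epochs:
    - duration_ms: 1000.0
      amplitude: -1.0
    - duration_ms: 1000.0
      amplitude: 8.0
    - duration_ms: 1000.0
      amplitude: -1.0
ic1_line: Fast0
inter_sweep_interval_s: 10.0
slow_latency_jitter_ms: 0.0
channel_solution_um:
  1:
  - 0.0
  - 0.0
  2:
  - 0.0
  - 2.5
  3:
  - 0.0
  - 5.0
  4:
  - 0.0
  - 10.0
  5:
  - 1.0
  - 0.0
  6:
  - 3.0
  - 0.0
  7:
  - 10.0
  - 0.0
  8:
  - 30.0
  - 0.0
biology:
  kind: patch
  emax_pa: 500.0
  ec50_um: 10.0
  hill_h: 1.0
  ki_um: 5.0
  tau_on_ms: 20.0
  tau_off_ms: 50.0
  rin_mohm: 100.0
  rs_mohm: 10.0
  cm_pf: 33.0
  noise_sd: 0.0
  rng_seed: 0
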
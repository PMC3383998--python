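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
  Slow1:
    line: Slow1
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
  Fast1:
    line: Fast1
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
  Fast0:
    line: Fast0
    mode: analog
    n_channels: 2
    volts_per_channel: 1.0
    valves_per_channel: 1
    port: Port1
    bit_base: 0
    valve_switch_time_ms: 1.0
    binary4_convention: 8ch
    flush_duration_s: 10.0
    amplitude_is_volts: false
transport: {}
sweep_defs:
  P0sweep:
    name: P0sweep
    duration_ms: 300.0
    sample_rate_hz: 10000.0
    s0_train: null
    s1_train: null
    ic0_steps: []
    ic1_epochs:
    - duration_ms: 100.0
      amplitude: -1.0
    - duration_ms: 50.0
      amplitude: 0.0
    - duration_ms: 150.0
      amplitude: -1.0
  P1sweep:
    name: P1sweep
    duration_ms: 300.0
    sample_rate_hz: 10000.0
    s0_train: null
    s1_train: null
    ic0_steps: []
    ic1_epochs:
    - duration_ms: 100.0
      amplitude: -1.0
    - duration_ms: 50.0
      amplitude: 2.0
    - duration_ms: 150.0
      amplitude: -1.0
ic1_line: Fast0
inter_sweep_interval_s: 5.0
slow_latency_jitter_ms: 0.0
channel_solution_um: {}
stepper:
  tubes:
  - 0
  - 1
  - 2
  fast0_volts_per_tube: 1.0
  move_time_ms: 1.0
  feeding_line:
    0: Slow0
    1: Slow1
    2: Fast1
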
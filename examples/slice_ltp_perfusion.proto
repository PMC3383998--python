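# sequential slice LTP experiment with automated perfusion: inhibitor on
# for the first train, washed out for the second
MainProtocol
  Perfuse Slow0 1
  Loop 99999 continuous
    P0sweep
  EndLoop
  Perfuse Slow0 2
  Loop 8
    P0sweep
  EndLoop
  T0sweep
  Loop 3
    P0sweep
  EndLoop
  Perfuse Slow0 1
  Loop 8
    P0sweep
  EndLoop
  T0sweep
  Loop 8
    P0sweep
  EndLoop
EndProtocol

[labels]
Slow0 1 = ACSF
Slow0 2 = CaMKII Inhibitor
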
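# sequential script: uncheck the baseline loop once stable, then the whole
# stimulation sequence runs unattended
MainProtocol
  Loop 99999 continuous
    P0sweep
  EndLoop
  T0sweep
  Loop 11
    P0sweep
  EndLoop
  T0sweep
  Loop 8
    P0sweep
  EndLoop
EndProtocol
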
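# circular script: continuous baseline loop; induction trains are evoked
# manually with single-sweep run controls
MainProtocol
  Loop 99999 continuous
    P0sweep
  EndLoop
EndProtocol
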
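# circular script with a RunOnce block: checking its Run control delivers
# one induction train inside the baseline loop
MainProtocol
  Loop 99999 continuous
    P0sweep
    RunOnce
      T0sweep
    EndRunOnce
  EndLoop
EndProtocol
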
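MainProtocol
  Perfuse Fast0 1  # Antagonist 1
  Delay 10
  Loop 3
    P0sweep
    P1sweep
    T0sweep
    T1sweep
  EndLoop
EndProtocol

[sweeps]
P0sweep = duration_ms=3000 rate_hz=2000 epochs=-1:1000,4:1000,-1:1000
P1sweep = duration_ms=3000 rate_hz=2000 epochs=-1:1000,5:1000,-1:1000
T0sweep = duration_ms=3000 rate_hz=2000 epochs=-1:1000,6:1000,-1:1000
T1sweep = duration_ms=3000 rate_hz=2000 epochs=-1:1000,7:1000,-1:1000

[labels]
Fast0 1 = Antagonist 1
Fast0 4 = Antagonist 1 + Agonist 1
Fast0 5 = Antagonist 1 + Agonist 2
Fast0 6 = Antagonist 1 + Agonist 3
Fast0 7 = Antagonist 1 + Agonist 4

[link]
next = fast_perfusion2.proto
autostart = true
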
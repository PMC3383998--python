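MainProtocol
  Perfuse Fast0 2  # Antagonist 2
  Delay 10
  Loop 3
    P0sweep
    P1sweep
    T0sweep
    T1sweep
  EndLoop
EndProtocol

[sweeps]
P0sweep = duration_ms=3000 rate_hz=2000 epochs=-1:1000,8:1000,-1:1000
P1sweep = duration_ms=3000 rate_hz=2000 epochs=-1:1000,9:1000,-1:1000
T0sweep = duration_ms=3000 rate_hz=2000 epochs=-1:1000,10:1000,-1:1000
T1sweep = duration_ms=3000 rate_hz=2000 epochs=-1:1000,11:1000,-1:1000

[labels]
Fast0 2 = Antagonist 2
Fast0 8 = Antagonist 2 + Agonist 1
Fast0 9 = Antagonist 2 + Agonist 2
Fast0 10 = Antagonist 2 + Agonist 3
Fast0 11 = Antagonist 2 + Agonist 4

[link]
next = fast_perfusion3.proto
autostart = true
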
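MainProtocol
  Perfuse Fast0 3  # Antagonist 3
  Delay 10
  Loop 3
    P0sweep
    P1sweep
    T0sweep
    T1sweep
  EndLoop
EndProtocol

[sweeps]
P0sweep = duration_ms=3000 rate_hz=2000 epochs=-1:1000,12:1000,-1:1000
P1sweep = duration_ms=3000 rate_hz=2000 epochs=-1:1000,13:1000,-1:1000
T0sweep = duration_ms=3000 rate_hz=2000 epochs=-1:1000,14:1000,-1:1000
T1sweep = duration_ms=3000 rate_hz=2000 epochs=-1:1000,15:1000,-1:1000

[labels]
Fast0 3 = Antagonist 3
Fast0 12 = Antagonist 3 + Agonist 1
Fast0 13 = Antagonist 3 + Agonist 2
Fast0 14 = Antagonist 3 + Agonist 3
Fast0 15 = Antagonist 3 + Agonist 4
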
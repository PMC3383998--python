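# tightly bound antagonist: perfuse each antagonist channel, then apply the
# four agonist channels during the four sweeps
MainProtocol
  Perfuse Fast0 1
  Delay 10
  P0sweep
  P1sweep
  T0sweep
  T1sweep
  Perfuse Fast0 2
  P0sweep
  P1sweep
  T0sweep
  T1sweep
  Perfuse Fast0 3
  P0sweep
  P1sweep
  T0sweep
  T1sweep
  Perfuse Fast0 4
  P0sweep
  P1sweep
  T0sweep
  T1sweep
EndProtocol

[labels]
Fast0 1 = Antagonist 1
Fast0 2 = Antagonist 2
Fast0 3 = Antagonist 3
Fast0 4 = Antagonist 4
Fast0 5 = Agonist 1
Fast0 6 = Agonist 2
Fast0 7 = Agonist 3
Fast0 8 = Agonist 4
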
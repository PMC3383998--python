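# triple-line stepper: Tube0<-Slow0 and Tube2<-Fast1 carry agonists, the
# antagonist flows from Tube1<-Slow1; the Fast0 analog output steps the
# tube assembly during P0 (to Tube0) and P1 (to Tube2) sweeps
MainProtocol
  Perfuse Slow1 1
  Perfuse Fast0 1
  Perfuse Slow0 1
  P0sweep
  Perfuse Slow0 2
  P0sweep
  Perfuse Fast1 1
  P1sweep
  Perfuse Fast1 2
  P1sweep
  Perfuse Slow1 2
  Perfuse Slow0 1
  P0sweep
  Perfuse Slow0 2
  P0sweep
  Perfuse Fast1 1
  P1sweep
  Perfuse Fast1 2
  P1sweep
EndProtocol

[labels]
Slow1 1 = Antag1
Slow1 2 = Antag2
Slow0 1 = Ag1
Slow0 2 = Ag2
Fast1 1 = Ag3
Fast1 2 = Ag4
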
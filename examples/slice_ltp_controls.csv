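# uncheck the baseline loop after 3 sweeps
sweep=3,uncheck_loop,loop=0
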
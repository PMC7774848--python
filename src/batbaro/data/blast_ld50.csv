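species,mass_g,ld50_Pa
mouse,20.7,184000
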
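species,mass_g,delta_p_Pa,duration_s,hemorrhage_pct,mortality_pct
rat,168,-45500,0.05,10,0
rat,168,-48000,1.9,20,0
rat,168,-52000,0.0021,20,0
rat,168,-55000,0.10,30,0
rat,168,-57900,0.50,40,0
rat,168,-58600,0.021,50,10
rat,168,-62000,0.10,60,20
rat,168,-68000,0.05,70,30
rat,168,-75000,0.01,80,50
rat,168,-82000,0.005,90,70
rat,168,-86500,0.0021,100,80
rabbit,2500,-70000,0.05,60,30
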
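# Regional soil backgrounds (Q0, mg/kg dry soil), soil bulk density (g/cm3),
# organic fertilizer application rate (t/hm2/yr) and survey sample counts.
region,n_samples,rho_b,IR_f,Cr,Ni,Cu,Zn,As,Cd,Pb
north,48,1.35,33.92,51.60,25.75,20.50,67.30,8.65,0.091,17.65
northwest,55,1.18,80.30,65.70,32.55,22.45,69.25,12.33,0.115,20.43
northeast,14,1.41,115.89,52.65,22.10,18.55,75.55,7.65,0.093,26.50
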
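# Route-specific reference doses (mg/kg/day) and carcinogenic slope factors
# (kg day/mg, IRIS/US-EPA). SF blank = metal not assessed as a carcinogen here.
metal,RfD_f,RfD_s,RfD_b,SF
Cr,3.00e-3,2.9e-5,6.00e-5,4.20e1
Ni,2.00e-2,2.00e-2,5.40e-3,8.40e-1
Cu,4.00e-2,4.00e-2,1.20e-2,
Zn,3.00e-1,3.00e-1,6.00e-2,
As,3.00e-4,3.00e-4,1.20e-3,1.51e1
Cd,1.00e-3,1.00e-3,1.00e-5,6.30
Pb,3.50e-3,3.50e-3,5.20e-4,
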
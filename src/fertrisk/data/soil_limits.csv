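# GB15618-2018 agricultural-soil risk-control limits, dry land at pH > 7.5 (mg/kg).
metal,limit
Cr,250
Ni,190
Cu,100
Zn,300
As,25
Cd,0.6
Pb,170
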
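# Adult exposure-model constants and per-metal absorption coefficients.
# Scalar rows leave `metal` blank. Fractions are dimensionless in [0,1].
parameter,metal,value,unit
IR_p,,100,mg/day
EF_a,,250,day/yr
ED_a,,25,yr
BW,,56.8,kg
LT,,26280,day
EV,,1,1/day
SA,,1.614,m2
mu,,0.18,fraction
eta,,0.2,mg/cm2
omega,,0.15,mg/m3
IR_b,,14.5,m3/day
f_spod,,0.8,fraction
EFOD_a,,87.5,day/yr
f_spid,,0.5,fraction
EFID_a,,262.5,day/yr
beta,Cr,2.5e-2,fraction
beta,Ni,1.6e-2,fraction
beta,Cu,1.0,fraction
beta,Zn,1.0,fraction
beta,As,1.0,fraction
beta,Cd,5.0e-2,fraction
beta,Pb,1.0,fraction
gamma,Cr,1.0e-3,fraction
gamma,Ni,1.6e-2,fraction
gamma,Cu,1.0e-3,fraction
gamma,Zn,6.0e-4,fraction
gamma,As,1.0e-3,fraction
gamma,Cd,1.0e-3,fraction
gamma,Pb,2.08e-5,fraction
theta,Cr,1.0,fraction
theta,Ni,0.016,fraction
theta,Cu,0.3,fraction
theta,Zn,0.2,fraction
theta,As,1.0,fraction
theta,Cd,0.01,fraction
theta,Pb,0.15,fraction
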
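# Regional summary statistics of the fertilizer survey (mg/kg dry weight):
# observed range, mean, median, sample SD and coefficient of variation (%).
region,metal,range_low,range_high,mean,median,sd,cv_percent
north,Cr,6.53,151.15,24.14,17.02,22.55,93.43
north,Ni,3.54,49.35,17.01,16.90,8.57,50.38
north,Cu,0.76,378.32,75.19,44.85,83.83,111.50
north,Zn,0.50,1595.42,581.91,478.11,429.65,73.83
north,As,1.54,23.96,7.76,6.96,4.89,63.02
north,Cd,0.04,5.25,0.79,0.38,1.09,138.36
north,Pb,5.08,151.09,24.47,15.46,27.27,111.46
northwest,Cr,2.74,36.34,12.26,10.75,6.75,55.03
northwest,Ni,2.94,35.11,12.21,10.98,6.49,53.17
northwest,Cu,4.55,355.52,34.20,19.84,49.72,145.39
northwest,Zn,4.11,1748.01,174.08,86.71,297.55,170.92
northwest,As,1.55,21.00,5.30,4.92,3.04,57.35
northwest,Cd,0.03,1.73,0.35,0.31,0.29,82.75
northwest,Pb,1.60,55.98,13.05,11.36,9.23,70.70
northeast,Cr,6.43,63.46,23.75,17.47,17.89,75.35
northeast,Ni,4.33,19.09,11.09,11.23,4.59,41.39
northeast,Cu,4.69,155.68,46.53,23.02,46.83,100.64
northeast,Zn,16.09,493.15,124.53,60.86,145.93,117.19
northeast,As,2.93,17.19,8.93,9.08,4.50,50.40
northeast,Cd,0.05,1.00,0.26,0.17,0.26,100.42
northeast,Pb,4.43,29.34,10.99,9.73,6.49,59.09
northern,Cr,2.74,151.15,18.51,13.03,17.27,93.28
northern,Ni,2.94,49.35,14.05,12.05,7.62,54.23
northern,Cu,0.76,378.32,52.49,31.67,67.97,129.50
northern,Zn,0.50,1748.01,335.47,144.14,401.56,119.70
northern,As,1.54,23.96,6.74,5.96,4.27,63.37
northern,Cd,0.03,5.25,0.52,0.31,0.76,146.32
northern,Pb,1.60,151.09,17.49,12.41,19.50,111.50
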
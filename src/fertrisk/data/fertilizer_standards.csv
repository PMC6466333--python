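# Maximum acceptable trace-metal concentrations for compost / organic fertilizer
# (mg/kg dry weight) by jurisdiction. Blank cells = metal not regulated.
jurisdiction_id,label,Cr,Ni,Cu,Zn,As,Cd,Pb,source
mauritius,Mauritius,50,50,,300,10,3,100,MS 164 (2010)
us_uscc,United States,1200,420,1500,2800,41,39,300,USCC-2001
us_washington,"United States, Washington",,210,750,1400,20,10,150,"WSDA, 2009"
canada_A,Canada A,210,62,400,700,13,3,150,CCME-2005
canada_B,Canada B,1060,180,757,1850,75,20,500,CAN/BNQ/CCME/AAFC
eu_organic,EU organic agriculture,70,25,70,200,,0.7,45,Biowaste Directory
eu_ecological,EU ecological standards,100,50,100,300,10,1,100,Biowaste Directory
eu_soil_amendment,EU soil amendment,100,50,100,300,,1,100,Biowaste Directory
uk,United Kingdom,100,50,200,400,,1.5,200,BSI-PAS 100-2011
france,France,120,60,300,600,,3,180,NF U44-051
netherlands,Netherlands,50,20,90,290,,1,100,Amended National Fertilizer Act from 2008
italy,Italy,,50,150,500,,1.5,140,Law on Fertilizer L 748/84
belgium,Belgium,100,50,150,400,20,2,150,Royal Decree
denmark,Denmark,,30,1000,4000,25,0.8,,Statutory Order Nr.1650
spain_A,Spain A,70,25,70,200,,0.7,45,Spain RD 506-2013
spain_B,Spain B,250,90,300,500,,2,150,Spain RD 506-2013
spain_C,Spain C,300,100,400,1000,,3,200,Spain RD 506-2013
germany_I,Germany I,70,35,70,300,,1,100,Biowaste Ordinance
germany_II,Germany II,100,50,100,400,,1.5,150,Biowaste Ordinance
switzerland,Switzerland,100,30,100,400,,1,120,Swiss Federal Council-2013
nz_compost,New Zealand compost,50,10,25,75,5,0.7,65,SDU-1991
nz_clean_compost,New Zealand clean compost,50,20,60,200,15,1,100,SDU-1991
aureli_A_plus,Aureli A+,70,25,70,200,,0.7,45,"SWD 64/F1-EN,2016"
aureli_A,Aureli A,70,60,150,500,,1,120,"SWD 64/F1-EN,2016"
australia,Australia,400,60,200,250,20,3,200,Compost Ordinance/AS 4454-2012
malaysia,Malaysia,200,150,,,,5,300,MS 1517-2012
india,India,50,50,,1000,10,3,150,"World Bank, 1997"
indonesia,Indonesia,50,50,,300,10,3,100,Ministry of Environment and Forests
japan,Japan,500,300,,,50,5,100,Fertilizer Management Act
korea,Korea,300,50,500,900,5,5,150,Fertilizer Management Act
hongkong_organic,Hong Kong organic agriculture,100,50,300,600,10,1,100,"Hong Kong ORC, 2005"
hongkong_general,Hong Kong general agricultural use,210,62,700,1300,13,3,150,"Hong Kong ORC, 2005"
hongkong_nonagricultural,Hong Kong nonagricultural use,1200,420,1500,2800,41,19,300,"Hong Kong ORC, 2005"
taiwan_livestock,Taiwan livestock and poultry composting,150,25,100,500,25,2,150,Fertilizer Management Act
taiwan_general,Taiwan general compost,150,25,100,250,25,2,150,Fertilizer Management Act
taiwan_misc,Taiwan miscellaneous compost,150,25,100,250,25,2,150,Fertilizer Management Act
china_ny525,Mainland China,300,,,,30,3,100,NY525-2012
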
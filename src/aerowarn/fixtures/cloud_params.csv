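criterion,level,Ex,En,He
PM2.5,I,17.5,11.67,1.17
PM2.5,II,55,13.33,1.33
PM2.5,III,95,13.33,1.33
PM2.5,IV,132.5,11.67,1.17
PM2.5,V,200,33.33,3.33
PM2.5,VI,291.99,28.00,2.80
PM10,I,25,16.67,1.67
PM10,II,100,33.33,3.33
PM10,III,200,33.33,3.33
PM10,IV,300,33.33,3.33
PM10,V,385,23.33,2.33
PM10,VI,457.95,25.30,2.53
O3,I,5,3.33,0.33
O3,II,85,50,5
O3,III,187.5,18.33,1.83
O3,IV,240,16.67,1.67
O3,V,532.5,178.33,17.83
O3,VI,988.8,125.86,12.59
CO,I,1,0.67,0.07
CO,II,3,0.67,0.07
CO,III,9,3.33,0.33
CO,IV,19,3.33,0.33
CO,V,30,4,0.4
CO,VI,44.21,5.47,0.55
NO2,I,20,13.33,1.33
NO2,II,60,13.33,1.33
NO2,III,130,33.33,3.33
NO2,IV,230,33.33,3.33
NO2,V,422.5,95,9.5
NO2,VI,707,94.67,9.47
SO2,I,25,16.67,1.67
SO2,II,100,33.33,3.33
SO2,III,200,33.33,3.33
SO2,IV,362.5,75,7.5
SO2,V,637.5,108.33,10.83
SO2,VI,989.97,126.65,12.67
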
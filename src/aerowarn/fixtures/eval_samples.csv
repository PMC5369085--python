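case,date,PM2.5,PM10,O3,CO,NO2,SO2
A_1,2015-07-01 01:00,28.7706,55.7602,67.3450,0.9697,25.8604,10.2004
A_2,2015-07-01 23:00,72.9066,107.0337,165.4987,1.1086,20.4798,11.1226
A_3,2015-07-02 09:00,8.4205,20.8968,82.3072,0.4267,20.5176,10.7273
A_4,2015-08-02 17:00,47.5483,69.4576,175.0633,0.7634,22.8088,6.7971
A_5,2015-08-14 20:00,127.6426,178.7458,217.2556,1.1993,25.2613,13.9264
A_6,2015-08-15 00:00,154.4614,211.3916,228.8058,1.3244,17.0485,16.1272
A_7,2015-09-01 01:00,17.9037,34.8418,78.1009,0.6857,24.9247,7.6599
A_8,2015-10-01 08:00,20.5887,37.0588,95.6089,1.0228,21.8282,4.3759
A_9,2015-10-05 13:00,75.7741,135.5992,157.9036,1.1049,25.8181,21.8493
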
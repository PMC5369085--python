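criterion,z,entropy,omega,W
PM2.5,0.3,4.6692,0.2348,0.4292
PM10,0.3,5.0828,0.1917,0.3505
O3,0.233,5.1281,0.0621,0.0881
CO,0.1,6.9810,0.0721,0.0439
NO2,0.033,4.0407,0.1730,0.0348
SO2,0.033,4.1733,0.2662,0.0535
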
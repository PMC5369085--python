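criterion,c2,c1,c0,bmax_vi
PM2.5,8.21,1.21,31,333.99
PM10,-4.29,119.7,-68,495.91
O3,54.64,-159.4,167,1177.6
CO,1.43,0.23,-0.4,52.42
NO2,35,-85,99,849
SO2,41.07,-63.93,85,1179.94
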
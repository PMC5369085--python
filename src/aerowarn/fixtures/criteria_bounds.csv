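level,PM2.5,PM10,O3,CO,NO2,SO2
I,35,50,10,2,40,50
II,75,150,160,4,80,150
III,115,250,215,14,180,250
IV,150,350,265,24,280,475
V,250,420,800,36,565,800
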
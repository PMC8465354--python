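village,informants,use_reports,taxa_identified,rf
Chota Bungus,7,361,67,62.62
Ringbala,8,174,54,50.47
Indradhook,21,223,49,45.79
Dudi,12,127,34,31.78
Machil,8,388,77,71.96
Lalpora,16,172,56,52.34
Warnow,18,86,29,27.1
Chuntiwari,12,94,36,33.64
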
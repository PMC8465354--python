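row_label,le_count,gt_count
Chuntiwari,7,13
Dudi,8,12
Indradhook,12,21
Khurhamma,4,8
Lalpora,10,12
Machil,6,8
Chota Bungus,9,10
Warnow,13,18
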
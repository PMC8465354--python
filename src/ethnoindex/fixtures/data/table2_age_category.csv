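row_label,le_count,gt_count
<=30,22,0
31-40,9,0
41-50,12,6
51-60,12,8
61-70,10,11
71-80,4,8
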
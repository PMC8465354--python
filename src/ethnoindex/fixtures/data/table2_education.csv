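row_label,le_count,gt_count
Illiterate,15,18
Primary,8,5
Middle,18,5
Matric,11,3
SeniorSecondary,9,1
Graduate,8,1
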
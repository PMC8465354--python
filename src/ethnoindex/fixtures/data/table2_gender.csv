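row_label,le_count,gt_count
F,15,20
M,54,13
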
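row_label,le_count,gt_count
Dard,21,12
Kashmiri,19,12
Gujjar,9,29
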
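factor,statistic,p_value
gender,0.885,0.347
place,14.516,0.043
community,2.12,0.347
education,13.734,0.017
age_category,25.673,0.001
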
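category,n_t,nt_pct,n_ur,nur_pct,icf
GAS,28,26.17,262,16.19,0.9
CAR,13,12.15,155,9.58,0.92
DER,19,17.76,203,12.55,0.91
GYN,9,8.41,101,6.24,0.92
NER,6,5.61,74,4.57,0.93
PAR,1,0.93,7,0.43,1.0
CAN,10,9.35,132,8.16,0.93
RES,29,27.1,243,15.02,0.88
SKE,21,19.63,175,10.82,0.89
MET,6,5.61,70,4.33,0.93
ETH,7,6.54,40,2.47,0.85
EY,5,4.67,56,3.46,0.93
ENT,6,5.61,53,3.28,0.9
FVR,6,5.61,54,3.34,0.91
IB,1,0.93,6,0.37,1.0
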
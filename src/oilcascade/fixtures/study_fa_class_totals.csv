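sample_id,treatment,t_P_h,ufa,mufa,pufa
C-0,C,0,90.40,62.58,27.82
C-16,C,16,89.78,64.47,25.31
C-32,C,32,89.11,66.32,22.79
CA-2-0,CA-2,0,90.40,62.58,27.82
CA-2-16,CA-2,16,89.81,63.65,26.16
CA-2-32,CA-2,32,89.04,66.49,22.55
CA-4-0,CA-4,0,90.40,62.58,27.82
CA-4-16,CA-4,16,89.94,63.64,26.30
CA-4-32,CA-4,32,89.83,66.60,23.23
CA-7-0,CA-7,0,90.40,62.58,27.82
CA-7-16,CA-7,16,90.32,64.12,26.20
CA-7-32,CA-7,32,89.55,65.58,23.97
TB-2-0,TB-2,0,90.40,62.58,27.82
TB-2-16,TB-2,16,89.87,64.31,25.56
TB-2-32,TB-2,32,89.30,66.53,22.77
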
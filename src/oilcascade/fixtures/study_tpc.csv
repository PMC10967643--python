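treatment,t_P_h,tpc_percent
C,0,7.0
C,8,11.0
C,16,18.5
C,24,23.0
C,32,35.5
CA-2,0,7.5
CA-2,8,10.5
CA-2,16,16.5
CA-2,24,22.0
CA-2,32,32.5
CA-4,0,7.5
CA-4,8,10.5
CA-4,16,17.0
CA-4,24,23.0
CA-4,32,30.5
CA-7,0,7.5
CA-7,8,10.5
CA-7,16,16.0
CA-7,24,20.5
CA-7,32,26.0
TB-2,0,7.5
TB-2,8,10.0
TB-2,16,17.5
TB-2,24,22.0
TB-2,32,32.0
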
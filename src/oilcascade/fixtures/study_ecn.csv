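treatment,t_P_h,ecn
C,0,16.13
C,8,16.17
C,16,16.17
C,24,16.21
C,32,16.23
CA-2,0,16.14
CA-2,8,16.18
CA-2,16,16.15
CA-2,24,16.18
CA-2,32,16.22
CA-4,0,16.13
CA-4,8,16.13
CA-4,16,16.17
CA-4,24,16.21
CA-4,32,16.26
CA-7,0,16.13
CA-7,8,16.20
CA-7,16,16.20
CA-7,24,16.20
CA-7,32,16.22
TB-2,0,16.13
TB-2,8,16.18
TB-2,16,16.18
TB-2,24,16.21
TB-2,32,16.22
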
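treatment,t_P_h,a,b,r2_lioumbas,mu0,Ea,r2_arrhenius
C,0,6.32,-0.19,0.999,0.04,16684.93,0.935
C,8,6.48,-0.20,1.000,0.04,17161.38,0.935
C,16,6.79,-0.21,0.998,0.04,17679.87,0.933
C,24,6.88,-0.21,1.000,0.11,14825.43,0.858
C,32,7.10,-0.22,1.000,0.18,13704.19,0.812
CA-2,0,6.23,-0.20,0.999,0.04,16684.93,0.935
CA-2,8,6.50,-0.20,0.999,0.05,16595.06,0.925
CA-2,16,6.70,-0.21,0.999,0.04,17343.72,0.930
CA-2,24,6.87,-0.21,0.999,0.05,16752.26,0.910
CA-2,32,7.19,-0.22,1.000,0.03,18683.22,0.939
CA-4,0,6.32,-0.19,0.999,0.04,16684.93,0.935
CA-4,8,6.42,-0.20,1.000,0.03,17916.81,0.953
CA-4,16,6.72,-0.21,0.999,0.04,17556.30,0.936
CA-4,24,6.82,-0.21,1.000,0.03,18168.82,0.948
CA-4,32,7.06,-0.22,1.000,0.12,14762.37,0.839
CA-7,0,6.23,-0.19,0.999,0.04,16684.93,0.935
CA-7,8,6.43,-0.20,1.000,0.06,15756.17,0.912
CA-7,16,6.70,-0.21,0.999,0.04,17343.72,0.930
CA-7,24,6.87,-0.21,1.000,0.04,17587.39,0.936
CA-7,32,7.19,-0.22,0.999,0.09,15588.09,0.860
TB-2,0,6.23,-0.20,0.999,0.04,16684.93,0.935
TB-2,8,6.43,-0.20,1.000,0.05,16425.37,0.925
TB-2,16,6.71,-0.21,1.000,0.03,18052.69,0.949
TB-2,24,6.92,-0.21,0.999,0.07,15994.97,0.886
TB-2,32,7.09,-0.22,1.000,0.12,14842.00,0.845
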
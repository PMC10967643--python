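sample_id,treatment,t_P_h,fa_code,percent
C-0,C,0,C16:0,4.51
C-0,C,0,C16:1,0.15
C-0,C,0,C18:0,1.49
C-0,C,0,C18:1,62.43
C-0,C,0,C18:2,20.36
C-0,C,0,C20:0,0.45
C-0,C,0,C18:3n3,7.46
C-0,C,0,C22:0,0.24
C-16,C,16,C16:0,4.83
C-16,C,16,C16:1,0.17
C-16,C,16,C18:0,1.62
C-16,C,16,C18:1,64.30
C-16,C,16,C18:2,19.03
C-16,C,16,C20:0,0.49
C-16,C,16,C18:3n3,6.28
C-16,C,16,C22:0,0.30
C-32,C,32,C16:0,5.13
C-32,C,32,C16:1,0.21
C-32,C,32,C18:0,1.80
C-32,C,32,C18:1,66.11
C-32,C,32,C18:2,17.88
C-32,C,32,C20:0,0.53
C-32,C,32,C18:3n3,4.91
C-32,C,32,C22:0,0.32
CA-2-0,CA-2,0,C16:0,4.51
CA-2-0,CA-2,0,C16:1,0.15
CA-2-0,CA-2,0,C18:0,1.49
CA-2-0,CA-2,0,C18:1,62.43
CA-2-0,CA-2,0,C18:2,20.36
CA-2-0,CA-2,0,C20:0,0.45
CA-2-0,CA-2,0,C18:3n3,7.46
CA-2-0,CA-2,0,C22:0,0.24
CA-2-16,CA-2,16,C16:0,4.79
CA-2-16,CA-2,16,C16:1,0.16
CA-2-16,CA-2,16,C18:0,1.61
CA-2-16,CA-2,16,C18:1,63.49
CA-2-16,CA-2,16,C18:2,19.62
CA-2-16,CA-2,16,C20:0,0.49
CA-2-16,CA-2,16,C18:3n3,6.54
CA-2-16,CA-2,16,C22:0,0.28
CA-2-32,CA-2,32,C16:0,5.37
CA-2-32,CA-2,32,C16:1,0.18
CA-2-32,CA-2,32,C18:0,1.77
CA-2-32,CA-2,32,C18:1,66.31
CA-2-32,CA-2,32,C18:2,17.77
CA-2-32,CA-2,32,C20:0,0.56
CA-2-32,CA-2,32,C18:3n3,4.78
CA-2-32,CA-2,32,C22:0,0.32
CA-4-0,CA-4,0,C16:0,4.51
CA-4-0,CA-4,0,C16:1,0.15
CA-4-0,CA-4,0,C18:0,1.49
CA-4-0,CA-4,0,C18:1,62.43
CA-4-0,CA-4,0,C18:2,20.36
CA-4-0,CA-4,0,C20:0,0.45
CA-4-0,CA-4,0,C18:3n3,7.46
CA-4-0,CA-4,0,C22:0,0.24
CA-4-16,CA-4,16,C16:0,4.76
CA-4-16,CA-4,16,C16:1,0.17
CA-4-16,CA-4,16,C18:0,1.61
CA-4-16,CA-4,16,C18:1,63.47
CA-4-16,CA-4,16,C18:2,19.52
CA-4-16,CA-4,16,C20:0,0.48
CA-4-16,CA-4,16,C18:3n3,6.78
CA-4-16,CA-4,16,C22:0,0.28
CA-4-32,CA-4,32,C16:0,5.02
CA-4-32,CA-4,32,C16:1,0.18
CA-4-32,CA-4,32,C18:0,1.70
CA-4-32,CA-4,32,C18:1,66.42
CA-4-32,CA-4,32,C18:2,17.92
CA-4-32,CA-4,32,C20:0,0.51
CA-4-32,CA-4,32,C18:3n3,5.31
CA-4-32,CA-4,32,C22:0,0.30
CA-7-0,CA-7,0,C16:0,4.51
CA-7-0,CA-7,0,C16:1,0.15
CA-7-0,CA-7,0,C18:0,1.49
CA-7-0,CA-7,0,C18:1,62.43
CA-7-0,CA-7,0,C18:2,20.36
CA-7-0,CA-7,0,C20:0,0.45
CA-7-0,CA-7,0,C18:3n3,7.46
CA-7-0,CA-7,0,C22:0,0.24
CA-7-16,CA-7,16,C16:0,4.58
CA-7-16,CA-7,16,C16:1,0.16
CA-7-16,CA-7,16,C18:0,1.68
CA-7-16,CA-7,16,C18:1,63.96
CA-7-16,CA-7,16,C18:2,19.60
CA-7-16,CA-7,16,C20:0,0.46
CA-7-16,CA-7,16,C18:3n3,6.60
CA-7-16,CA-7,16,C22:0,0.24
CA-7-32,CA-7,32,C16:0,5.01
CA-7-32,CA-7,32,C16:1,0.17
CA-7-32,CA-7,32,C18:0,1.78
CA-7-32,CA-7,32,C18:1,65.41
CA-7-32,CA-7,32,C18:2,18.23
CA-7-32,CA-7,32,C20:0,0.50
CA-7-32,CA-7,32,C18:3n3,5.74
CA-7-32,CA-7,32,C22:0,0.33
TB-2-0,TB-2,0,C16:0,4.51
TB-2-0,TB-2,0,C16:1,0.15
TB-2-0,TB-2,0,C18:0,1.49
TB-2-0,TB-2,0,C18:1,62.43
TB-2-0,TB-2,0,C18:2,20.36
TB-2-0,TB-2,0,C20:0,0.45
TB-2-0,TB-2,0,C18:3n3,7.46
TB-2-0,TB-2,0,C22:0,0.24
TB-2-16,TB-2,16,C16:0,4.87
TB-2-16,TB-2,16,C16:1,0.15
TB-2-16,TB-2,16,C18:0,1.60
TB-2-16,TB-2,16,C18:1,64.16
TB-2-16,TB-2,16,C18:2,19.15
TB-2-16,TB-2,16,C20:0,0.50
TB-2-16,TB-2,16,C18:3n3,6.41
TB-2-16,TB-2,16,C22:0,0.26
TB-2-32,TB-2,32,C16:0,5.16
TB-2-32,TB-2,32,C16:1,0.17
TB-2-32,TB-2,32,C18:0,1.72
TB-2-32,TB-2,32,C18:1,66.36
TB-2-32,TB-2,32,C18:2,17.64
TB-2-32,TB-2,32,C20:0,0.55
TB-2-32,TB-2,32,C18:3n3,5.13
TB-2-32,TB-2,32,C22:0,0.33
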
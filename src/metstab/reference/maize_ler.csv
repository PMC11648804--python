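trait,system,season,genotype,LER
CWH,IC1,1,H1,1.25
CWH,IC1,1,H2,1.33
CWH,IC1,1,H3,1.22
CWH,IC1,1,H4,1.31
CWH,IC1,1,H5,1.36
CWH,IC1,1,H6,1.34
CWH,IC1,1,H7,1.39
CWH,IC1,1,H8,1.32
CWH,IC1,1,H9,1.48
CWH,IC1,1,H10,1.44
CWH,IC1,1,H11,1.07
CWH,IC1,1,H12,1.28
CWH,IC1,1,H13,1.29
CWH,IC1,1,H14,1.51
CWH,IC1,1,H15,1.34
CWH,IC1,1,H16,1.39
CWH,IC1,1,H17,1.2
CWH,IC1,1,H18,1.25
CWH,IC1,1,H19,1.25
CWH,IC1,1,H20,1.34
CWH,IC1,1,T1,1.98
CWH,IC1,1,T2,1.33
CWH,IC1,1,T3,1.54
CWH,IC1,1,T4,1.22
CWH,IC1,2,H1,1.37
CWH,IC1,2,H2,1.34
CWH,IC1,2,H3,1.43
CWH,IC1,2,H4,1.11
CWH,IC1,2,H5,1.25
CWH,IC1,2,H6,1.3
CWH,IC1,2,H7,1.27
CWH,IC1,2,H8,1.44
CWH,IC1,2,H9,1.42
CWH,IC1,2,H10,1.17
CWH,IC1,2,H11,1.03
CWH,IC1,2,H12,1.14
CWH,IC1,2,H13,1.43
CWH,IC1,2,H14,1.2
CWH,IC1,2,H15,0.85
CWH,IC1,2,H16,0.92
CWH,IC1,2,H17,1.05
CWH,IC1,2,H18,1.52
CWH,IC1,2,H19,1.39
CWH,IC1,2,H20,1.16
CWH,IC1,2,T1,1.21
CWH,IC1,2,T2,1.31
CWH,IC1,2,T3,1.65
CWH,IC1,2,T4,1.12
CWH,IC2,1,H1,0.96
CWH,IC2,1,H2,0.88
CWH,IC2,1,H3,0.73
CWH,IC2,1,H4,0.92
CWH,IC2,1,H5,0.78
CWH,IC2,1,H6,0.9
CWH,IC2,1,H7,1.05
CWH,IC2,1,H8,0.7
CWH,IC2,1,H9,0.84
CWH,IC2,1,H10,0.8
CWH,IC2,1,H11,0.64
CWH,IC2,1,H12,0.67
CWH,IC2,1,H13,0.81
CWH,IC2,1,H14,0.83
CWH,IC2,1,H15,0.81
CWH,IC2,1,H16,0.89
CWH,IC2,1,H17,0.86
CWH,IC2,1,H18,0.98
CWH,IC2,1,H19,0.72
CWH,IC2,1,H20,1.05
CWH,IC2,1,T1,1.23
CWH,IC2,1,T2,0.72
CWH,IC2,1,T3,1.01
CWH,IC2,1,T4,0.64
CWH,IC2,2,H1,0.94
CWH,IC2,2,H2,0.78
CWH,IC2,2,H3,1.17
CWH,IC2,2,H4,0.84
CWH,IC2,2,H5,0.72
CWH,IC2,2,H6,0.75
CWH,IC2,2,H7,0.93
CWH,IC2,2,H8,1.07
CWH,IC2,2,H9,0.95
CWH,IC2,2,H10,0.84
CWH,IC2,2,H11,0.84
CWH,IC2,2,H12,0.79
CWH,IC2,2,H13,0.96
CWH,IC2,2,H14,0.84
CWH,IC2,2,H15,0.76
CWH,IC2,2,H16,0.63
CWH,IC2,2,H17,0.75
CWH,IC2,2,H18,1.06
CWH,IC2,2,H19,0.8
CWH,IC2,2,H20,0.74
CWH,IC2,2,T1,0.65
CWH,IC2,2,T2,0.93
CWH,IC2,2,T3,0.88
CWH,IC2,2,T4,1.05
GY,IC1,1,H1,1.08
GY,IC1,1,H2,1.28
GY,IC1,1,H3,1.16
GY,IC1,1,H4,1.37
GY,IC1,1,H5,1.57
GY,IC1,1,H6,1.42
GY,IC1,1,H7,1.37
GY,IC1,1,H8,1.32
GY,IC1,1,H9,1.36
GY,IC1,1,H10,1.32
GY,IC1,1,H11,1.24
GY,IC1,1,H12,1.3
GY,IC1,1,H13,1.32
GY,IC1,1,H14,1.4
GY,IC1,1,H15,1.4
GY,IC1,1,H16,1.38
GY,IC1,1,H17,1.34
GY,IC1,1,H18,1.29
GY,IC1,1,H19,1.29
GY,IC1,1,H20,1.36
GY,IC1,1,T1,1.66
GY,IC1,1,T2,1.23
GY,IC1,1,T3,1.32
GY,IC1,1,T4,1.16
GY,IC1,2,H1,1.41
GY,IC1,2,H2,1.3
GY,IC1,2,H3,1.23
GY,IC1,2,H4,1.08
GY,IC1,2,H5,1.15
GY,IC1,2,H6,1.27
GY,IC1,2,H7,1.19
GY,IC1,2,H8,1.37
GY,IC1,2,H9,1.5
GY,IC1,2,H10,1.61
GY,IC1,2,H11,1.01
GY,IC1,2,H12,1.55
GY,IC1,2,H13,1.43
GY,IC1,2,H14,1.15
GY,IC1,2,H15,1.06
GY,IC1,2,H16,1.06
GY,IC1,2,H17,0.9
GY,IC1,2,H18,1.52
GY,IC1,2,H19,1.46
GY,IC1,2,H20,1.07
GY,IC1,2,T1,0.96
GY,IC1,2,T2,1.27
GY,IC1,2,T3,1.53
GY,IC1,2,T4,1.19
GY,IC2,1,H1,0.63
GY,IC2,1,H2,0.75
GY,IC2,1,H3,0.52
GY,IC2,1,H4,0.73
GY,IC2,1,H5,0.73
GY,IC2,1,H6,0.56
GY,IC2,1,H7,1.01
GY,IC2,1,H8,0.65
GY,IC2,1,H9,1.03
GY,IC2,1,H10,0.68
GY,IC2,1,H11,0.74
GY,IC2,1,H12,0.6
GY,IC2,1,H13,0.86
GY,IC2,1,H14,0.76
GY,IC2,1,H15,0.78
GY,IC2,1,H16,0.77
GY,IC2,1,H17,0.72
GY,IC2,1,H18,0.91
GY,IC2,1,H19,0.8
GY,IC2,1,H20,0.87
GY,IC2,1,T1,0.88
GY,IC2,1,T2,0.5
GY,IC2,1,T3,0.68
GY,IC2,1,T4,0.87
GY,IC2,2,H1,0.79
GY,IC2,2,H2,0.82
GY,IC2,2,H3,1.02
GY,IC2,2,H4,0.96
GY,IC2,2,H5,0.75
GY,IC2,2,H6,0.72
GY,IC2,2,H7,0.84
GY,IC2,2,H8,0.9
GY,IC2,2,H9,1.11
GY,IC2,2,H10,1.16
GY,IC2,2,H11,0.81
GY,IC2,2,H12,1.01
GY,IC2,2,H13,0.75
GY,IC2,2,H14,0.91
GY,IC2,2,H15,0.68
GY,IC2,2,H16,0.68
GY,IC2,2,H17,0.64
GY,IC2,2,H18,1.22
GY,IC2,2,H19,0.89
GY,IC2,2,H20,0.81
GY,IC2,2,T1,0.57
GY,IC2,2,T2,1.08
GY,IC2,2,T3,0.7
GY,IC2,2,T4,1.23
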
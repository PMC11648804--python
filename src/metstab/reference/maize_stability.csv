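trait,genotype,mean,asv,rank_mean,rank_asv,gsi,rank_gsi
CWH,H1,8.756975,0.2277562,3,4,7,1
CWH,H2,7.79801,0.6156969,6,16,22,7
CWH,H3,8.981728,1.6107813,2,22,24,9
CWH,H4,7.900556,0.1651713,5,2,7,1
CWH,H5,7.339649,0.6140148,12,15,27,13
CWH,H6,7.244609,0.1818535,15,3,18,5
CWH,H7,7.129239,0.485574,16,11,27,13
CWH,H8,7.067195,0.5711775,17,14,31,20
CWH,H9,6.516049,0.3053621,23,5,28,17
CWH,H10,6.740432,1.1629429,20,19,39,23
CWH,H11,7.611432,1.1809348,8,20,28,17
CWH,H12,9.624568,2.4395253,1,24,25,11
CWH,H13,7.401204,0.7551079,10,17,27,13
CWH,H14,6.833395,0.456236,18,9,27,13
CWH,H15,7.279993,0.475011,14,10,24,9
CWH,H16,7.763774,0.383488,7,7,14,3
CWH,H17,7.337333,0.8336439,13,18,31,20
CWH,H18,7.390317,0.3435281,11,6,17,4
CWH,H19,6.760216,0.5573242,19,13,32,22
CWH,H20,6.733796,0.4081656,21,8,29,19
CWH,T1,5.936111,1.908563,24,23,47,24
CWH,T2,7.517938,0.5359845,9,12,21,6
CWH,T3,8.091738,1.3465013,4,21,25,11
CWH,T4,6.548452,0.152659,22,1,23,8
GY,H1,4.794568,1.859091,2,18,20,5
GY,H2,4.712901,1.5837208,3,15,18,4
GY,H3,5.287778,5.2063954,1,24,25,12
GY,H4,4.286235,1.0168983,16,9,25,12
GY,H5,4.52463,1.9948371,5,20,25,12
GY,H6,4.073333,0.8361593,21,8,29,19
GY,H7,4.173889,1.0237023,18,10,28,18
GY,H8,4.349753,1.8637358,12,19,31,21
GY,H9,4.308518,1.5853866,13,16,29,19
GY,H10,4.230926,0.745642,17,7,24,10
GY,H11,4.303364,2.1327229,14,21,35,22
GY,H12,4.110124,1.6735872,19,17,36,23
GY,H13,4.465864,1.197241,6,11,17,3
GY,H14,4.04963,0.5389847,22,2,24,10
GY,H15,4.287984,0.6993901,15,5,20,5
GY,H16,4.42432,1.377584,8,14,22,8
GY,H17,4.399321,0.3045344,9,1,10,1
GY,H18,4.464198,1.3022106,7,13,20,5
GY,H19,4.377037,1.3002327,10,12,22,8
GY,H20,4.077346,0.7095017,20,6,26,15
GY,T1,4.021049,2.4462294,23,23,46,24
GY,T2,4.684568,2.2056537,4,22,26,15
GY,T3,4.370926,0.5914402,11,4,15,2
GY,T4,3.849568,0.5650185,24,3,27,17
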
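source,df,ss_CWH,ss_GY
Rep,12,24.74,3.6
Season,1,3.83,106.19
System,2,3514.60,1412.49
Season:System,2,0.85,68.44
Genotype,23,285.1,37.78
Genotype:Season,23,141.38,66.81
Genotype:System,46,317.3,94.27
Genotype:Season:System,46,220.04,109.82
Error,276,601.38,118.41
Total,431,5109.21,2017.81
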
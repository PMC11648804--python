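trait,mean,min,max,sd,cv_pct
CWH,7.43,2.57,21.11,3.44,19.87
GY,4.36,1.44,14.15,2.16,15.02
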
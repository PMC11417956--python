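id,n,mean,median,sd,se,min,max,cv_percent
Female1,13,3.3,3.06,0.96,0.28,1.86,5.2,29.1
Female2,12,3.75,3.90,0.64,0.18,2.44,4.86,17.1
Female3,11,4.69,4.42,1.49,0.45,3.03,7.06,31.8
Female4,12,1.14,1.10,0.24,0.07,0.87,1.73,21.1
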
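spline,window,fgv_beta,fgv_lci,fgv_uci,ctx_beta,ctx_lci,ctx_uci
1,0-2.5,-2.10,-3.89,-0.23,-3.99,-6.65,-1.70
2,2.5-4.5,-1.12,-2.55,0.33,-0.24,-1.77,1.34
3,4.5-7,-2.90,-3.29,-2.51,-1.95,-2.72,-1.18
4,7-9,-1.07,-1.45,-0.68,-1.15,-1.93,-0.35
5,9-11,-0.52,-0.90,-0.13,-0.99,-1.73,-0.23
6,11-13,-2.57,-4.13,-1.02,-1.05,-2.45,0.32
7,13-15,-2.28,-4.27,-0.33,-1.88,-5.25,1.67
8,15-17.5,-2.50,-4.98,0.04,1.46,-3.81,6.31
9,17.5-20,-1.66,-3.85,0.49,-1.17,-3.87,1.61
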
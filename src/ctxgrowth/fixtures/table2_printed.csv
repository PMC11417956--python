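spline,window,sex,fgv_beta,fgv_lci,fgv_uci,ctx_beta,ctx_lci,ctx_uci
1,0-2.5,F,1.52,-1.38,3.91,1.85,-0.29,4.36
2,2.5-4.5,F,1.18,-0.70,2.78,0.27,-0.97,1.50
3,4.5-7,F,2.02,-0.20,3.75,0.21,-0.62,1.05
4,7-9,F,1.03,-0.99,2.62,0.11,-0.75,0.92
5,9-11,F,-0.15,-2.32,1.64,-0.05,-0.89,0.78
6,11-13,F,-0.24,-2.44,1.66,0.10,-1.04,1.25
7,13-15,F,0.96,-1.36,2.97,0.08,-3.19,3.19
8,15-17.5,F,-1.20,-3.67,1.02,-3.09,-7.29,1.26
9,17.5-20,F,0.76,-1.72,3.02,-0.64,-2.87,1.73
1,0-2.5,M,-0.58,-5.27,3.68,-2.14,-5.94,1.56
2,2.5-4.5,M,0.06,-3.25,3.11,0.03,-1.73,1.27
3,4.5-7,M,-0.88,-5.18,1.24,-1.74,-2.90,-0.97
4,7-9,M,-0.04,-2.43,1.94,-1.04,-1.70,-0.35
5,9-11,M,-0.67,-2.22,0.39,-1.04,-1.96,-0.26
6,11-13,M,-2.81,-6.15,0.64,-0.95,-2.75,0.26
7,13-15,M,-1.32,-6.55,1.64,-1.80,-4.70,1.10
8,15-17.5,M,-3.70,-8.65,1.06,-1.63,-5.13,0.18
9,17.5-20,M,-0.90,-4.54,2.51,-1.81,-4.04,0.42
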
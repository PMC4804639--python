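item,n_asd,asd_mean,asd_sd,n_td,td_mean,td_sd,t,p,d,significant
availability,21,95.3,5.5,35,97.2,3.1,1.45,0.157,0.47,0
A.eyes,21,64.9,22.9,35,80.9,19.0,2.83,0.007,0.79,1
A.mouth,21,11.5,10.1,35,7.5,8.3,1.59,0.118,0.45,0
B.eyes,21,46.7,31.6,35,77.4,24.1,3.83,0.001,1.15,1
B.mouth,21,22.1,19.2,35,7.0,15.7,3.02,0.005,0.89,1
C.eyes,21,36.3,27.3,35,49.3,21.7,1.96,0.055,0.55,0
C.mouth,21,36.2,25.7,35,27.7,20.5,1.36,0.179,0.38,0
D.eyes,21,28.9,36.4,35,60.0,31.0,3.40,0.001,0.96,1
D.mouth,21,38.2,34.6,35,17.7,22.3,2.43,0.021,0.76,1
E.eyes,21,37.1,34.7,35,49.4,27.3,1.48,0.145,0.42,0
E.mouth,21,36.8,32.4,35,28.3,21.8,1.06,0.298,0.33,0
F.upright,21,47.7,13.4,35,52.7,16.3,1.18,0.243,0.33,0
F.inverted,21,49.7,13.8,35,44.7,15.6,1.21,0.232,0.34,0
G.people,21,47.6,23.1,35,67.2,16.6,3.39,0.002,1.03,1
G.geometry,21,44.7,22.3,35,29.8,15.9,2.67,0.012,0.82,1
H.geometry,21,33.0,23.9,35,21.9,15.3,2.13,0.038,0.60,1
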
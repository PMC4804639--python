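item,auc,ci_low,ci_high,direction,cutoff
A.eyes,0.73,0.60,0.87,asd_below,71
A.mouth,0.63,0.48,0.78,asd_above,7
B.eyes,0.80,0.68,0.92,asd_below,81
B.mouth,0.79,0.65,0.92,asd_above,8
C.eyes,0.65,0.50,0.81,asd_below,20
C.mouth,0.59,0.43,0.75,asd_above,32
D.eyes,0.75,0.60,0.89,asd_below,32
D.mouth,0.66,0.50,0.82,asd_above,16
E.eyes,0.62,0.46,0.80,asd_below,11
E.mouth,0.54,0.38,0.71,asd_above,38
F.upright,0.59,0.44,0.75,asd_below,50
F.inverted,0.59,0.43,0.75,asd_above,48
G.people,0.74,0.60,0.88,asd_below,57
G.geometry,0.69,0.54,0.84,asd_above,37
H.geometry,0.62,0.46,0.78,asd_above,31
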
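measure,group,n,mean,sd,t,p
age,ASD,21,27.6,7.7,1.28,0.212
age,TD,35,25.2,4.5,,
fsiq,ASD,20,99.8,13.5,,
viq,ASD,20,103.3,13.3,,
piq,ASD,20,96.4,16.0,,
srs,ASD,17,111.8,18.5,11.46,0.001
srs,TD,35,53.6,16.9,,
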
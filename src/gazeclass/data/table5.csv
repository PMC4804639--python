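label,B.eyes,D.eyes,G.people,asd_n,asd_pct,td_n,td_pct
none,0,0,0,1,4.8,18,51.4
blinking_only,1,0,0,2,9.5,5,14.3
silent_only,0,1,0,0,0.0,2,5.7
people_only,0,0,1,1,4.8,3,8.6
blinking_silent,1,1,0,5,23.8,3,8.6
blinking_people,1,0,1,2,9.5,0,0.0
silent_people,0,1,1,1,4.8,1,2.9
all_three,1,1,1,9,42.9,3,8.6
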
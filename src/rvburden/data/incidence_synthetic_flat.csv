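age_lo,age_hi,rate
0,5,0.000135
5,10,0.000135
10,15,0.000135
15,20,0.000135
20,25,0.000135
25,30,0.000135
30,35,0.000135
35,40,0.000135
40,45,0.000135
45,50,0.000135
50,55,0.000135
55,60,0.000135
60,65,0.000135
65,70,0.000135
70,75,0.000135
75,80,0.000135
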
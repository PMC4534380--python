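coherence,r,s
0,18,56.9
3.2,11.2,23.7
6.4,7.4,13.6
9,6.7,11.9
12,4.8,8.5
25.6,2.3,3.8
51.2,0.55,0.16
75,0.30,0.14
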
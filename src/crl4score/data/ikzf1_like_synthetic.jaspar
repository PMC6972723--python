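>SYN0001 IKZF1_like_synthetic
A [  2  1  0  0 90 85 30 ]
C [  8  2  1  3  4  5 20 ]
G [ 10 95 97 95  4  6 35 ]
T [ 80  2  2  2  2  4 15 ]
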
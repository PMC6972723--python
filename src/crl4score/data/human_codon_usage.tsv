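codon	count
TTT	176
TTC	203
TTA	77
TTG	129
CTT	132
CTC	196
CTA	72
CTG	396
ATT	160
ATC	208
ATA	75
ATG	220
GTT	110
GTC	145
GTA	71
GTG	281
TCT	152
TCC	177
TCA	122
TCG	44
CCT	175
CCC	198
CCA	169
CCG	69
ACT	131
ACC	189
ACA	151
ACG	61
GCT	184
GCC	277
GCA	158
GCG	74
TAT	122
TAC	153
CAT	109
CAC	151
CAA	123
CAG	342
AAT	170
AAC	191
AAA	244
AAG	319
GAT	218
GAC	251
GAA	290
GAG	396
TGT	106
TGC	126
TGG	132
CGT	45
CGC	104
CGA	62
CGG	114
AGT	121
AGC	195
AGA	122
AGG	120
GGT	108
GGC	222
GGA	165
GGG	165
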
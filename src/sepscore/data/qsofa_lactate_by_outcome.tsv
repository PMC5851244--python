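level	count_survivor	count_nonsurvivor
0	158	5
1	138	9
2	68	18
3	39	15
4	4	3
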
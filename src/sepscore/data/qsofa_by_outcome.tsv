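level	count_survivor	count_nonsurvivor
0	223	11
1	129	16
2	51	20
3	4	3
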
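level	count_survivor	count_nonsurvivor
0	243	14
1	164	36
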
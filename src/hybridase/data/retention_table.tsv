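temperature	medium	crosses	hybrids	n_sc_mtdna	n_su_mtdna
28	YPD	22	21	10	11
28	Gly	22	19	19	0
16	YPD	26	19	13	6
16	Gly	22	5	5	0
10	YPD	48	17	5	12
10	Gly	62	1	0	1
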
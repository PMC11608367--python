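n_forms	eudicots	monocots	basal_angiosperm	gymnosperm	marchantiophyta	bryophyta	lycopodiophyta	charophyta	chlorophytae
2	126	74	0	0	0	13	0	0	3
3	44	14	0	0	0	0	0	0	0
4	21	8	0	0	0	4	0	0	0
5	2	2	0	0	1	1	0	0	0
6	4	1	0	0	0	0	0	0	0
7	2	0	0	0	0	0	0	0	0
8	2	0	0	0	0	0	0	0	0
9	0	0	0	0	0	0	0	0	0
10	2	1	0	0	0	2	0	0	0
11	0	0	0	0	0	0	0	0	0
12	1	0	0	0	0	1	0	0	0
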
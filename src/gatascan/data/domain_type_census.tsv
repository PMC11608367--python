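dtype	eudicots	monocots	basal_angiosperm	gymnosperm	marchantiophyta	bryophyta	lycopodiophyta	charophyta	chlorophytae
IVb	2867	1079	15	33	7	36	3	8	83
IVc	642	241	2	6	2	48	1	1	7
IVp	224	81	3	4	0	0	2	1	8
IV4	40	0	0	0	0	0	0	0	0
IVa	26	0	0	0	0	0	0	0	0
IVe	12	11	0	0	1	4	2	3	33
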
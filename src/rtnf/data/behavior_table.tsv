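subject	group	metr_index	te
P01	parallel	11	2.2
P02	parallel	1	0.8
P03	parallel	18	1.2
P04	parallel	14	0.8
P05	parallel	1	2.1
P06	parallel	18	2.6
P07	parallel	8	0.8
P08	parallel	5	0.6
P09	parallel	14	1.4
P10	parallel	17	0.2
S01	serial	8	2.7
S02	serial	18	3.7
S03	serial	11	2.1
S04	serial	6	1.2
S05	serial	2	1.9
S06	serial	2	2.1
S07	serial	5	1.4
S08	serial	6	2.3
S09	serial	16	1.0
S10	serial	2	4.2
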
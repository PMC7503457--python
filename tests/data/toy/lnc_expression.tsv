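gene_id	S01	S02	S03	S04	S05	S06	S07	S08	S09	S10	S11	S12	S13	S14	S15	S16	S17	S18	S19	S20
lnc1	16.0	15.0	14.0	13.0	12.0	11.0	10.0	9.0	8.0	7.0	6.0	5.0	4.0	3.0	2.0	1.0	5.0	5.0	5.0	5.0
lnc2	2.0	4.5	3.1	6.2	2.8	5.5	3.9	4.8	2.2	6.8	3.3	5.1	2.6	4.2	6.5	3.6	4.0	4.0	4.0	4.0
lnc3	7.1	2.3	5.4	3.8	6.6	2.9	4.4	6.1	3.2	5.8	2.5	4.9	6.9	3.5	5.2	2.1	4.0	4.0	4.0	4.0
lnc4	0.2	0.4	0.1	0.3	0.5	0.2	0.6	0.1	0.4	0.3	0.2	0.5	2.0	3.0	2.5	3.5	0.1	0.1	0.1	0.1
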
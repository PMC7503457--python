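gene_id	S01	S02	S03	S04	S05	S06	S07	S08	S09	S10	S11	S12	S13	S14	S15	S16	S17	S18	S19	S20
mrna1	5.0	5.3	5.1	5.2	4.5	4.4	4.3	4.2	4.1	4.0	3.9	3.8	1.2	1.1	1.0	0.9	3.0	3.0	3.0	3.0
mrna2	4.1	2.2	5.6	3.0	4.8	2.5	5.2	3.4	4.4	2.8	5.9	3.7	4.0	2.1	5.4	3.2	4.0	4.0	4.0	4.0
mrna3	3.3	5.7	2.4	4.6	3.0	5.3	2.7	4.3	3.6	5.0	2.2	4.9	3.8	5.5	2.9	4.1	4.0	4.0	4.0	4.0
mrna4	5.0	5.1	5.2	5.3	5.0	5.1	5.2	5.3	5.0	5.1	5.2	5.3	5.0	5.1	5.2	5.3	5.0	5.0	5.0	5.0
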
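gene_id	S01	S02	S03	S04	S05	S06	S07	S08	S09	S10	S11	S12	S13	S14	S15	S16	S17	S18	S19	S20
mir1	1.0	1.1	0.9	1.05	1.5	1.6	1.7	1.8	2.2	2.3	2.4	2.5	2.9	3.0	3.1	3.2	2.0	2.0	2.0	2.0
mir2	3.3	3.4799999999999995	3.3599999999999994	3.42	2.9999999999999996	2.94	2.8799999999999994	2.82	2.7599999999999993	2.6999999999999997	2.6399999999999997	2.5799999999999996	1.02	0.96	0.8999999999999999	0.8400000000000001	2.0999999999999996	2.0999999999999996	2.0999999999999996	2.0999999999999996
mir3	3.0	1.2	4.1	2.0	3.6	1.5	4.4	2.4	3.2	1.8	4.7	2.7	3.9	1.1	4.9	2.2	3.0	3.0	3.0	3.0
mir4	5.0	5.0	5.0	5.0	5.0	5.0	5.0	5.0	5.0	5.0	5.0	5.0	5.0	5.0	5.0	5.0	5.0	5.0	5.0	5.0
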
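sample_id	purity
S01	0.9
S02	0.9
S03	0.9
S04	0.9
S05	0.9
S06	0.9
S07	0.9
S08	0.9
S09	0.9
S10	0.9
S11	0.9
S12	0.9
S13	0.9
S14	0.9
S15	0.9
S16	0.9
S17	0.8
S18	0.79
S19	0.5
S20	0.3
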
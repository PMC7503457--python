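sample_id	time	event
S01	269	1
S02	1570	0
S03	1343	1
S04	933	0
S05	922	1
S06	1731	0
S07	263	1
S08	1424	0
S09	482	1
S10	278	0
S11	1100	1
S12	1953	0
S13	1497	1
S14	1546	0
S15	1463	1
S16	1593	0
S17	1075	1
S18	343	0
S19	1695	1
S20	955	0
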
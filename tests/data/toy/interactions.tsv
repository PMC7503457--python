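mirna_id	target_id	target_class
mir1	lnc1	lncRNA
mir1	mrna1	mRNA
mir2	lnc1	lncRNA
mir2	mrna1	mRNA
mir3	lnc1	lncRNA
mir3	mrna1	mRNA
b01	lnc1	lncRNA
b01	mrna1	mRNA
b02	lnc1	lncRNA
b02	mrna1	mRNA
mir3	lnc3	lncRNA
b10	lnc3	lncRNA
b11	lnc3	lncRNA
b12	lnc3	lncRNA
b13	lnc3	lncRNA
mir3	mrna3	mRNA
b05	mrna3	mRNA
b06	mrna3	mRNA
b07	mrna3	mRNA
b08	mrna3	mRNA
b14	mrna-x	mRNA
b15	mrna-x	mRNA
b16	mrna-x	mRNA
b17	mrna-x	mRNA
b18	mrna-x	mRNA
b19	mrna-x	mRNA
b20	mrna-x	mRNA
b21	mrna-x	mRNA
b22	mrna-x	mRNA
b23	mrna-x	mRNA
b24	mrna-x	mRNA
b25	mrna-x	mRNA
b26	mrna-x	mRNA
b27	mrna-x	mRNA
b28	mrna-x	mRNA
b29	mrna-x	mRNA
b30	mrna-x	mRNA
b31	mrna-x	mRNA
b32	mrna-x	mRNA
b33	mrna-x	mRNA
b34	mrna-x	mRNA
b35	mrna-x	mRNA
b36	mrna-x	mRNA
b37	mrna-x	mRNA
b38	mrna-x	mRNA
b39	mrna-x	mRNA
b40	mrna-x	mRNA
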
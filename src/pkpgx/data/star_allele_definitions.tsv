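# Star-allele defining variants, transcribed from PharmVar-style definitions
# (https://www.pharmvar.org) restricted to the variants on the genotyping
# panel used by this package. The reference allele (*1) is implicit: absence
# of every defining variant. One row per (allele, defining variant).
# version: panel-2023-08
gene	allele	rsid	variant_allele
CYP2D6	*3	rs35742686	delA
CYP2D6	*4	rs3892097	A
CYP2D6	*4	rs1065852	T
CYP2D6	*6	rs5030655	delT
CYP2D6	*7	rs5030867	C
CYP2D6	*8	rs5030865	T
CYP2D6	*9	rs5030656	delTCT
CYP2D6	*10	rs1065852	T
CYP2D6	*14	rs5030865	A
CYP2D6	*17	rs28371706	T
CYP2D6	*41	rs28371725	A
SLCO1B1	*5	rs4149056	C
SLCO1B1	*15	rs4149056	C
SLCO1B1	*15	rs2306283	G
SLCO1B1	*37	rs2306283	G
UGT1A1	*80	rs887829	T
CYP2A6	*9	rs28399433	G
CYP2B6	*4	rs2279343	G
CYP2B6	*5	rs3211371	T
CYP2B6	*6	rs2279343	G
CYP2B6	*6	rs3745274	T
CYP2B6	*7	rs2279343	G
CYP2B6	*7	rs3745274	T
CYP2B6	*7	rs3211371	T
CYP2B6	*9	rs3745274	T
CYP2C8	*2	rs11572103	T
CYP2C8	*3	rs10509681	G
CYP2C8	*4	rs1058930	G
CYP2C9	*2	rs1799853	T
CYP2C9	*3	rs1057910	C
CYP2C19	*2	rs4244285	A
CYP2C19	*3	rs4986893	A
CYP2C19	*4	rs28399504	G
CYP2C19	*17	rs12248560	T
CYP3A4	*2	rs55785340	C
CYP3A4	*6	rs46464389	A
CYP3A4	*20	rs67666821	A
CYP3A4	*22	rs35599367	T
CYP3A5	*3	rs776746	G
CYP3A5	*6	rs10264272	A
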
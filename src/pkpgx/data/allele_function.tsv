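# Per-allele function assignments in the CPIC/DPWG style
# (https://cpicpgx.org, https://www.pharmgkb.org/page/pgxGeneRef), reduced to
# the alleles resolvable from the genotyping panel. "activity" is the CYP2D6
# (and CYP2C9) activity-score value; "function" is the qualitative class used
# by the two-way phenotype lookup. CYP2C8 assignments are provisional
# (literature-based, no CPIC guideline). UGT1A1*80 is a surrogate for *28.
# version: panel-2023-08
gene	allele	function	activity
CYP2D6	*1	normal	1
CYP2D6	*3	none	0
CYP2D6	*4	none	0
CYP2D6	*5	none	0
CYP2D6	*6	none	0
CYP2D6	*7	none	0
CYP2D6	*8	none	0
CYP2D6	*9	decreased	0.25
CYP2D6	*10	decreased	0.25
CYP2D6	*14	none	0
CYP2D6	*17	decreased	0.5
CYP2D6	*41	decreased	0.25
SLCO1B1	*1	normal
SLCO1B1	*5	decreased
SLCO1B1	*15	decreased
SLCO1B1	*37	normal
UGT1A1	*1	normal
UGT1A1	*80	decreased
CYP2A6	*1	normal
CYP2A6	*9	decreased
CYP2B6	*1	normal
CYP2B6	*4	increased
CYP2B6	*5	normal
CYP2B6	*6	decreased
CYP2B6	*7	decreased
CYP2B6	*9	decreased
CYP2C8	*1	normal
CYP2C8	*2	decreased
CYP2C8	*3	decreased
CYP2C8	*4	decreased
CYP2C9	*1	normal	1
CYP2C9	*2	decreased	0.5
CYP2C9	*3	none	0
CYP2C19	*1	normal
CYP2C19	*2	none
CYP2C19	*3	none
CYP2C19	*4	none
CYP2C19	*17	increased
CYP3A4	*1	normal
CYP3A4	*2	decreased
CYP3A4	*6	none
CYP3A4	*20	none
CYP3A4	*22	decreased
CYP3A5	*1	normal
CYP3A5	*3	none
CYP3A5	*6	none
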
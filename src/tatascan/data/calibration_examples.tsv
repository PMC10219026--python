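# Published TBP-promoter equilibrium dissociation constants for the printed
# worked-example promoter contexts (ancestral and minor alleles).  These are
# the calibration inputs for the default model coefficients.
gene	transcript	allele	rsid	sequence	kd_nM	se_nM
CRP	CRP-201	ancestral	norm	tgctttggatAtaaatccagg	2.26	0.23
CRP	CRP-201	minor	rs1660782480	tgctttggatGtaaatccagg	7.64	0.76
CRP	CRP-201	minor	rs1660782424	tgctttggataCaaatccagg	6.19	0.62
SERPINF1	SERPINF1-205	ancestral	norm	gagtgcaggtCgctttaagaa	10.21	0.92
SERPINF1	SERPINF1-205	minor	rs541151948:A	gagtgcaggtAgctttaagaa	7.27	0.51
SERPINF1	SERPINF1-205	minor	rs541151948:T	gagtgcaggtTgctttaagaa	8.53	0.77
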
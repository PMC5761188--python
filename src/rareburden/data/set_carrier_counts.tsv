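set	class	case_carriers	control_carriers	p	or	ci	test
GWAS_PROPOSED	LOF	17	4	0.008	3.89	1.26-15.95	FISHER
NEIGHBOURING	LOF	9	9	1	0.90	0.32-2.58	FISHER
TOTAL	LOF	26	13	0.077	1.83	0.90-3.90	FISHER
GWAS_PROPOSED	MISSENSE	287	251	0.679	1.05	0.86-1.28	CHISQ_YATES
NEIGHBOURING	MISSENSE	168	138	0.392	1.12	0.87-1.44	CHISQ_YATES
TOTAL	MISSENSE	406	353	0.512	1.07	0.89-1.28	CHISQ_YATES
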
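stratum	case_carriers	control_carriers	n_case	n_control	p	or	ci
ALL	406	353	1043	944	0.512	1.07	0.89-1.28
CONDEL	174	136	1043	944	0.182	1.19	0.93-1.53
POLYPHEN	198	164	1043	944	0.384	1.11	0.88-1.41
CADD15	225	173	1043	944	0.08	1.23	0.98-1.54
SIFT	171	131	1043	944	0.134	1.22	0.94-1.57
REVEL05	88	63	1043	944	0.163	1.29	0.91-1.83
ALL_FIVE	58	39	1043	944	0.170	1.37	0.89-2.13
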
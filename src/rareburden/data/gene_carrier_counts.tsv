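gene	criterion	lof_case	lof_control	lof_p	lof_or	lof_ci	mis_case	mis_control	mis_p	mis_or	mis_ci
TET2	GWAS_PROPOSED	5	2	0.456	2.27	0.37-23.87	20	18	1	1.01	0.50-2.03
NRIP1	GWAS_PROPOSED	3	0	0.251	Und	0.37-inf	21	17	0.632	1.12	0.56-2.28
RAD51B	GWAS_PROPOSED	2	0	0.501	Und	0.17-inf	6	4	0.756	1.36	0.32-6.57
SNX32	NEIGHBOURING	2	0	0.501	Und	0.17-inf	3	6	0.323	0.45	0.07-2.12
ZNF226	NEIGHBOURING	2	2	1	0.91	0.07-12.52	24	18	0.640	1.21	0.63-2.39
ADAM29	GWAS_PROPOSED	1	0	1	Und	0.02-inf	13	11	1	1.07	0.44-2.65
CASP8	GWAS_PROPOSED	1	0	1	Und	0.02-inf	8	2	0.113	3.64	0.72-35.26
CDKN2A	GWAS_PROPOSED	1	0	1	Und	0.02-inf	3	3	1	0.91	0.12-6.77
DCLRE1B	NEIGHBOURING	1	1	1	0.91	0.01-71.08	7	6	1	1.06	0.30-3.82
FTO	GWAS_PROPOSED	1	0	1	Und	0.02-inf	10	11	0.668	0.82	0.31-2.14
LGR6	GWAS_PROPOSED	1	0	1	Und	0.02-inf	16	8	0.217	1.82	0.73-4.94
MUS81	NEIGHBOURING	1	1	1	0.91	0.01-71.08	8	9	0.808	0.80	0.27-2.36
NFRKB	NEIGHBOURING	1	1	1	0.91	0.01-71.08	17	12	0.577	1.29	0.58-2.97
PDE4D	GWAS_PROPOSED	1	0	1	Und	0.02-inf	6	3	0.512	1.81	0.39-11.24
SETMAR	NEIGHBOURING	1	2	0.607	0.45	0.01-8.70	7	3	0.349	2.12	0.48-12.73
SLC4A7	GWAS_PROPOSED	1	0	1	Und	0.02-inf	14	10	0.682	1.27	0.52-3.21
USHBP1	NEIGHBOURING	1	1	1	0.91	0.01-71.08	14	11	0.841	1.15	0.48-2.82
CDKN2B	GWAS_PROPOSED	0	1	0.475	0	0-35.30	1	1	1	0.91	0.01-71.08
TCF7L2	GWAS_PROPOSED	0	1	0.475	0	0-35.30	5	8	0.406	0.56	0.14-1.96
TPK1	NEIGHBOURING	0	1	0.475	0	0-35.30	2	2	1	0.91	0.07-12.50
ZNF283	NEIGHBOURING						17	6	0.057	2.59	0.97-8.06
HNF4G	GWAS_PROPOSED						4	1	0.377	3.63	0.36-178.82
TERT	GWAS_PROPOSED						5	6	0.765	0.75	0.18-2.97
UNC13A	NEIGHBOURING						17	8	0.158	1.94	0.79-5.21
LSP1	GWAS_PROPOSED						11	15	0.327	0.66	0.27-1.55
XRCC1	NEIGHBOURING						6	12	0.153	0.45	0.14-1.30
ZMIZ1	GWAS_PROPOSED						15	11	0.694	1.24	0.53-3.00
EMID1	NEIGHBOURING						11	8	0.654	1.25	0.46-3.59
FGFR2	GWAS_PROPOSED						4	4	1	0.91	0.17-4.87
CCDC88C	GWAS_PROPOSED						38	45	0.219	0.76	0.47-1.20
ITPR1	NEIGHBOURING						17	20	0.507	0.77	0.37-1.55
MKL1	GWAS_PROPOSED						26	19	0.547	1.24	0.66-2.40
CHST9	GWAS_PROPOSED						7	9	0.617	0.70	0.22-2.13
PEX14	GWAS_PROPOSED						9	6	0.613	1.36	0.43-4.66
PAX9	GWAS_PROPOSED						3	7	0.207	0.39	0.06-1.70
PTHLH	GWAS_PROPOSED						3	1	0.626	2.72	0.22-142.85
CDCA7	GWAS_PROPOSED						5	3	0.729	1.51	0.29-9.76
MAP3K1	GWAS_PROPOSED						20	11	0.206	1.66	0.75-3.85
RANBP9	GWAS_PROPOSED						10	5	0.309	1.82	0.56-6.80
DNAJC1	GWAS_PROPOSED						8	9	0.808	0.80	0.27-2.36
TOX3	GWAS_PROPOSED						7	7	1	0.90	0.27-3.03
EPB41L5	NEIGHBOURING						8	8	1	0.90	0.29-2.78
ESR1	GWAS_PROPOSED						3	6	0.323	0.45	0.07-2.12
MDM4	GWAS_PROPOSED						7	3	0.349	2.12	0.48-12.73
CDYL2	GWAS_PROPOSED						11	5	0.217	2	0.64-7.37
TNP1	NEIGHBOURING						0	2	0.226	0	0-4.82
BABAM1	NEIGHBOURING						4	3	1	1.21	0.20-8.27
TGFBR2	GWAS_PROPOSED						4	3	1	1.21	0.20-8.27
ELL	GWAS_PROPOSED						9	5	0.430	1.63	0.49-6.23
NF2	NEIGHBOURING						12	5	0.150	2.19	0.71-7.95
KCNN4	NEIGHBOURING						8	4	0.393	1.82	0.49-8.27
DLX2	NEIGHBOURING						7	4	0.553	1.59	0.40-7.42
KAT5	NEIGHBOURING						3	2	1	1.36	0.16-16.29
COX11	GWAS_PROPOSED						2	1	1	1.81	0.09-106.93
EBF1	GWAS_PROPOSED						2	3	0.673	0.60	0.05-5.27
RAD23B	NEIGHBOURING						0	1	0.475	0	0-35.30
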
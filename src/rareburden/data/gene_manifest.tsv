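symbol	criterion	snp_ids
TERT	GWAS_PROPOSED	rs7726159;rs10069690;rs2736108
RAD51B	GWAS_PROPOSED	rs2588809;rs999737
TET2	GWAS_PROPOSED	rs9790517
ADAM29	GWAS_PROPOSED	rs6828523
FGFR2	GWAS_PROPOSED	rs2981579;rs11199914
PDE4D	GWAS_PROPOSED	rs1353747
EBF1	GWAS_PROPOSED	rs1432679
DNAJC1	GWAS_PROPOSED	rs7072776;rs11814448
RANBP9	GWAS_PROPOSED	rs204247
HNF4G	GWAS_PROPOSED	rs2943559;rs6472903
CASP8	GWAS_PROPOSED	rs1045485
TCF7L2	GWAS_PROPOSED	rs7904519
SLC4A7	GWAS_PROPOSED	rs4973768
MAP3K1	GWAS_PROPOSED	rs889312
ESR1	GWAS_PROPOSED	rs12662670;rs2046210
PAX9	GWAS_PROPOSED	rs2236007
CCDC88C	GWAS_PROPOSED	rs941764
CDKN2A	GWAS_PROPOSED	rs1011970
CDKN2B	GWAS_PROPOSED	rs1011970
FTO	GWAS_PROPOSED	rs17817449;rs11075995
ZMIZ1	GWAS_PROPOSED	rs704010
CDYL2	GWAS_PROPOSED	rs13329835
LSP1	GWAS_PROPOSED	rs3817198
CHST9	GWAS_PROPOSED	rs1436904;rs527616
PTHLH	GWAS_PROPOSED	rs10771399
TOX3	GWAS_PROPOSED	rs3803662
ELL	GWAS_PROPOSED	rs4808801
COX11	GWAS_PROPOSED	rs6504950
MKL1	GWAS_PROPOSED	rs6001930
NRIP1	GWAS_PROPOSED	rs2823093
MDM4	GWAS_PROPOSED	rs4245739
PEX14	GWAS_PROPOSED	rs616488
LGR6	GWAS_PROPOSED	rs6678914
TGFBR2	GWAS_PROPOSED	rs12493607
CDCA7	GWAS_PROPOSED	rs1550623
DLX2	NEIGHBOURING	rs2016394
SETMAR	NEIGHBOURING	rs6762644
ITPR1	NEIGHBOURING	rs6762644
RAD23B	NEIGHBOURING	rs10759243
TPK1	NEIGHBOURING	rs720475
TNP1	NEIGHBOURING	rs13387042
DCLRE1B	NEIGHBOURING	rs11552449
KAT5	NEIGHBOURING	rs3903072
SNX32	NEIGHBOURING	rs3903072
MUS81	NEIGHBOURING	rs3903072
NFRKB	NEIGHBOURING	rs11820646
XRCC1	NEIGHBOURING	rs3760982
KCNN4	NEIGHBOURING	rs3760982
ZNF283	NEIGHBOURING	rs3760982
ZNF226	NEIGHBOURING	rs3760982
USHBP1	NEIGHBOURING	rs8170;rs2363956
BABAM1	NEIGHBOURING	rs8170;rs2363956
UNC13A	NEIGHBOURING	rs8170;rs2363956
EMID1	NEIGHBOURING	rs132390
NF2	NEIGHBOURING	rs132390
EPB41L5	NEIGHBOURING	rs4849887
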
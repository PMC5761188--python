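symbol	cds_change	protein_change	dbsnp_id	case_carriers	control_carriers	consequence	evs_european_maf	exac_nfe_maf
ADAM29	c.2020A>T	p.Lys674Ter	-	1	0	Stop-gained	0	0
CASP8	c.379C>T	p.Arg127Ter	-	1	0	Stop-gained	0	0
CDKN2A	c.225_243delCGCCACTCTCACCCGACCC	p.Ala76CysfsTer64	-	1	0	Frame shift	0	0
CDKN2B	c.149_150delCG	p.Ala50AspfsTer36	-	0	1	Frame shift	0	<0.0001
DCLRE1B	c.189+1G>C	-	-	1	0	Splice donor	0	0
DCLRE1B	c.256G>T	p.Gly86Ter	-	0	1	Stop-gained	0	0
FTO	c.11delC	p.Pro5ArgfsTer13	-	1	0	Frame shift	0	0
LGR6	c.858-2A>C	-	-	1	0	Splice acceptor	<0.0001	<0.0001
MUS81	c.1314delC	p.Pro439LeufsTer6	-	1	0	Frame shift	0	0
MUS81	c.1062delC	p.Arg355GlyfsTer2	-	0	1	Frame shift	0	0
NFRKB	c.2149G>T	p.Glu717Ter	-	1	0	Stop-gained	0	0
NFRKB	c.794C>G	p.Ser265Ter	-	0	1	Stop-gained	0	<0.0001
NRIP1	c.40_41insT	p.Asp14ValfsTer25	-	1	0	Frame shift	0	0
NRIP1	c.2750C>G	p.Ser917Ter	-	1	0	Stop-gained	0	0
NRIP1	c.1968dupT	p.Gly657TrpfsTer5	-	1	0	Frame shift	0	0
PDE4D	c.2400_2410dupTGTCATAGATG	p.Asp804ValfsTer3	-	1	0	Frame shift	0	0
RAD51B	c.139C>T	p.Arg47Ter	rs200355697	2	0	Stop-gained	0	0.0001
SETMAR	c.823_826delAAAG	p.Glu276GlyfsTer2	-	1	0	Frame shift	0	<0.0001
SETMAR	c.706C>T	p.Arg236Ter	-	0	1	Stop-gained	0	0.0001
SETMAR	c.1635C>G	p.Tyr545Ter	-	0	1	Stop-gained	0	0
SLC4A7	c.1663G>T	p.Gly555Ter	-	1	0	Stop-gained	0	0
SNX32	c.1111C>T	p.Arg371Ter	-	1	0	Stop-gained	0	<0.0001
SNX32	c.825+2T>G	-	-	1	0	Splice donor	0	0
TCF7L2	c.1804_1805insAAT	p.Glu602_Glu603insTer	-	0	1	Stop-gained	0	0
TET2	c.1085_1086insT	p.Pro363SerfsTer6	-	1	0	Frame shift	0	0
TET2	c.2072delC	p.Thr691MetfsTer9	-	1	0	Frame shift	0	0
TET2	c.3646C>T	p.Arg1216Ter	-	1	0	Stop-gained	0	0
TET2	c.4361_4362insG	p.Arg1455GlnfsTer23	-	1	0	Frame shift	0	0
TET2	c.3812_3820delGCGCCTGTC	p.Cys1271_Gln1274delinsTer	-	1	0	Stop-gained	0	0
TET2	c.832C>T	p.Gln278Ter	-	0	1	Stop-gained	0	0
TET2	c.1458delC	p.Asn486LysfsTer11	-	0	1	Frame shift	0	0
TPK1	c.185+1G>A	-	-	0	1	Splice donor	0	0
USHBP1	c.1220+1G>T	-	rs144791770	1	0	Splice donor	0.0002	0.0001
USHBP1	c.258dupA	p.Val87SerfsTer103	-	0	1	Frame shift	0.0001	<0.0001
ZNF226	c.1229_1230delAA	p.Arg411SerfsTer11	-	1	0	Frame shift	0	0.0001
ZNF226	c.2239C>T	p.Arg747Ter	-	1	0	Stop-gained	0	0
ZNF226	c.2380G>T	p.Glu794Ter	rs201830106	0	1	Stop-gained	0.0007	0.0003
ZNF226	c.582delT	p.Asn194LysfsTer41	-	0	1	Frame shift	0	0
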
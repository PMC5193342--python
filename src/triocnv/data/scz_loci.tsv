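locus	cnv_type	chromosome	start_mb	end_mb	case_carriers	case_de_novo	grozeva	rees	szatkiewicz	chapman
1q21.1	del_or_dup	chr1	145	145.9	0	0	1	6	1	0
NRXN1	del	chr2	50	51.1	1	1	n/a	0	0	0
3q29	del	chr3	197.2	198.8	0	0	0	0	0	0
WBS	dup	chr7	72.4	73.8	1	1	n/a	1	0	n/a
VIPR2	dup	chr7	158.5	158.6	0	0	n/a	6	2	n/a
15q11.2	del	chr15	20.4	20.6	1	0	40	26	0	5
AS/PWS	dup	chr15	22.4	26.1	0	0	n/a	0	n/a	0
15q13.3	del	chr15	28.9	30.3	0	0	4	2	2	0
16p13.11	dup	chr16	15.4	16.2	2	0	25	12	6	2
16p11.2dist	del	chr16	28.7	29	0	0	n/a	2	1	n/a
16p11.2	dup	chr16	29.5	30.1	1	1	4	0	2	0
17p12	del	chr17	14.1	15.4	0	0	n/a	3	n/a	0
17q12	del	chr17	31.9	33.3	1	1	2	0	0	0
22q11.2	del	chr22	17.4	19.8	2	2	0	0	0	0
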
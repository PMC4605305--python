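event_id	gene_symbol	WT_U	WT_S	PSF_KD_S
LEF1	LEF1	36	88	48
DKFZp434I0612	DKFZp434I0612	46	61	24
LUC7L	LUC7L	31	66	32
AMOTL1	AMOTL1	70	86	58
BAT2L	BAT2L	8	38	11
MYO5A	MYO5A	59	77	54
PRPF3	PRPF3	18	41	19
TRA2A	TRA2A	33	50	32
PPIL5	PPIL5	34	56	40
NFYA	NFYA	5	28	15
BBX	BBX	14	25	10
SNHG3-RCC1.a	SNHG3-RCC1	36	55	42
ITGA6	ITGA6	34	44	32
C20orf72	C20orf72	80	70	82
HISPPD2A	HISPPD2A	26	9	21
USP33	USP33	33	21	35
KLC1	KLC1	93	77	91
HNRNPH3	HNRNPH3	78	64	80
ATP11C	ATP11C	44	32	48
GNAS	GNAS	73	62	80
MATR3	MATR3	80	68	85
SESTD1	SESTD1	67	33	51
C10orf28	C10orf28	42	32	53
PEX5L	PEX5L	87	77	96
WHSC1L1	WHSC1L1	40	29	49
NCOR2	NCOR2	81	66	86
CCDC7	CCDC7	53	38	61
ADNP	ADNP	84	69	92
DTNB	DTNB	27	12	36
CDCA7L	CDCA7L	37	21	48
CTTN	CTTN	73	43	70
SNHG3-RCC1.b	SNHG3-RCC1	44	25	53
APP	APP	89	63	92
C2orf33	C2orf33	46	25	56
RPGR	RPGR	76	64	95
TPIP	TPIP	80	59	92
KCNAB2	KCNAB2	33	22	57
SRPK2	SRPK2	48	32	68
OPA1	OPA1	52	33	75
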
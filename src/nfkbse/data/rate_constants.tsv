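reaction	symbol	order_class	nominal_value	source_ref	fitted_value
IKKa + IkBa -> IKKa_IkBa	Aa	a	0.2	[1]	0.1813
IKKa + IkBb -> IKKa_IkBb	Ab	a	0.05	[3]	0.02997
IKKa + IkBe -> IKKa_IkBe	Ae	a	0.05	[3]	0.04244
IKKa + IkBa_NFkB -> IKKa_IkBa_NFkB	Ba	a	1	[1]	1.024
IKKa + IkBb_NFkB -> IKKa_IkBb_NFkB	Bb	a	0.25	[3]	0.3683
IKKa + IkBe_NFkB -> IKKa_IkBe_NFkB	Be	a	0.25	[3]	0.42
NFkBn -> NFkBn + A20t	C1	b	0.0000005	[1]	0.000000506
0 -> A20t	C2	c	0	[1]	0
A20t -> 0	C3	b	0.0004	[1]	0.0002438
A20t -> A20t + A20	C4	b	0.5	[1]	0.5807
A20 -> 0	C5	b	0.0003	[1]	0.0003769
IKKa_IkBa -> IKKa + IkBa	Da	b	0.00125	[2]	0.002046
IKKa_IkBb -> IKKa + IkBb	Db	b	0.00175	[2]	0.0005609
IKKa_IkBe -> IKKa + IkBe	De	b	0.00175	[2]	0.002142
IKKa_IkBa_NFkB -> IKKa + IkBa_NFkB	Da	b	0.00125	[2]	0.002046
IKKa_IkBb_NFkB -> IKKa + IkBb_NFkB	Db	b	0.00175	[2]	0.000561
IKKa_IkBe_NFkB -> IKKa + IkBe_NFkB	De	b	0.00175	[2]	0.002142
IKKa_IkBa_NFkB -> IKKa_IkBa + NFkB	Ea	b	0.000001	[2]	0.00000144
IKKa_IkBb_NFkB -> IKKa_IkBb + NFkB	Eb	b	0.000001	[2]	0.00000124
IKKa_IkBe_NFkB -> IKKa_IkBe + NFkB	Ee	b	0.000001	[2]	0.00000064
IKKa_IkBa + NFkB -> IKKa_IkBa_NFkB	Fa	a	0.5	[2]	0.3789
IKKa_IkBb + NFkB -> IKKa_IkBb_NFkB	Fb	a	0.5	[2]	0.2135
IKKa_IkBe + NFkB -> IKKa_IkBe_NFkB	Fe	a	0.5	[2]	0.3528
IkBa_NFkB -> NFkB + IkBa	Ga	b	0.000001	[2]	0.00000064
IkBb_NFkB -> NFkB + IkBb	Gb	b	0.000001	[2]	0.00000044
IkBe_NFkB -> NFkB + IkBe	Ge	b	0.000001	[2]	0.00000069
IkBan_NFkBn -> NFkBn + IkBan	Ga	b	0.000001	[2]	0.00000064
IkBbn_NFkBn -> NFkBn + IkBbn	Gb	b	0.000001	[2]	0.00000044
IkBen_NFkBn -> NFkBn + IkBen	Ge	b	0.000001	[2]	0.00000069
IkBa + NFkB -> IkBa_NFkB	Ha	a	0.5	[2]	0.4593
IkBb + NFkB -> IkBb_NFkB	Hb	a	0.5	[2]	0.7753
IkBe + NFkB -> IkBe_NFkB	He	a	0.5	[2]	0.2895
IkBan + NFkBn -> IkBan_NFkBn	Ha	a	0.5	[2]	0.4593
IkBbn + NFkBn -> IkBbn_NFkBn	Hb	a	0.5	[2]	0.7753
IkBen + NFkBn -> IkBen_NFkBn	He	a	0.5	[2]	0.2895
NFkB -> NFkBn	I1	b	0.0025	[1]	0.003037
NFkBn -> NFkB	K01	b	0.00005	[3]	0.00005537
IKKn -> IKKa	K1	b	0.0025	[1]	0.003273
A20 + IKKa -> A20 + IKKi	K2	a	0.1	[1]	0.07075
IKKa -> IKKi	K3	b	0.0015	[1]	0.00202
0 -> IKKn	Kprod	c	0.000025	[1]	0.000009752
IKKn, IKKa, or IKKi -> 0	Kdeg	b	0.000125	[1]	0.0001561
Volume ratio of cytoplasm to nucleus	Kv		5	[1]	5
IkBan_NFkBn -> IkBa_NFkB	La	b	0.01	[1]	0.013979
IkBbn_NFkBn -> IkBb_NFkB	Lb	b	0.005	[3]	0.001567
IkBen_NFkBn -> IkBe_NFkB	Le	b	0.005	[3]	0.006583
IkBa_NFkB -> NFkB	Ma	b	0.000025	[1]	0.00002837
IkBb_NFkB -> NFkB	Mb	b	0.000025	[3]	0.00003609
IkBe_NFkB -> NFkB	Me	b	0.000025	[3]	0.00000866
Total NF-kB concentration	NFkB_total	d	0.06	[1]	0.06
IKKa_IkBa_NFkB -> IKKa + NFkB	Pa	b	0.1	[1]	0.12928
IKKa_IkBb_NFkB -> IKKa + NFkB	Pb	b	0.05	[3]	0.06454
IKKa_IkBe_NFkB -> IKKa + NFkB	Pe	b	0.05	[3]	0.08434
IkBan -> IkBa	Qa	b	0.0005	[1]	0.0005123
IkBbn -> IkBb	Qb	b	0.0005	[3]	0.0007398
IkBen -> IkBe	Qe	b	0.0005	[3]	0.0002184
IKKa_IkBa -> IKKa	Ra	b	0.1	[1]	0.123
IKKa_IkBb -> IKKa	Rb	b	0.1	[3]	0.03837
IKKa_IkBe -> IKKa	Re	b	0.1	[3]	0.1571
IkBan_NFkBn -> NFkBn	Sa	b	0.000001	[2]	0.00000037
IkBbn_NFkBn -> NFkBn	Sb	b	0.000001	[2]	0.000001131
IkBen_NFkBn -> NFkBn	Se	b	0.000001	[2]	0.000001037
NFkBn -> NFkBn + IkBat	Ua	b	0.0000005	[1]	0.000000279
NFkBn -> NFkBn + IkBbt	Ub	b	0	[2]	0
NFkBn -> NFkBn + IkBet	Ue	b	0.00000005	[3]	0.000000059
IkBa -> IkBan	Va	b	0.001	[1]	0.0009786
IkBb -> IkBbn	Vb	b	0.001	[3]	0.0004871
IkBe -> IkBen	Ve	b	0.001	[3]	0.00147
IkBa, IkBan -> 0	Wa	b	0.0001	[1]	0.000132
IkBb, IkBbn -> 0	Wb	b	0.0001	[3]	0.000133
IkBe, IkBen -> 0	We	b	0.0001	[3]	0.000042
IkBat -> IkBat + IkBa	Xa	b	0.5	[1]	0.4552
IkBbt -> IkBbt + IkBb	Xb	b	0.5	[3]	0.3828
IkBet -> IkBet + IkBe	Xe	b	0.5	[3]	0.3304
0 -> IkBat	Ya	c	0.00000005	[3]	0.000000084
0 -> IkBbt	Yb	c	0.000000005	[3]	0.00000000414
0 -> IkBet	Ye	c	0.000000005	[3]	0.00000000508
IkBat -> 0	Za	b	0.0004	[1]	0.0003375
IkBbt -> 0	Zb	b	0.0004	[3]	0.0002031
IkBet -> 0	Ze	b	0.0004	[3]	0.0004742
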
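case	category	chromosome	junction	side1	side2	repeat1	repeat2	mh	ins
P2109_190	Deletions only	5	1	16715951	16758649	AluSx	MIRb	3	0
P2109_190	Deletions only	5	2	16736554	16771433	AluJo	L1P5	0	3
P72	Deletions only	7	1	70609299	74047984	LTR26	AluSx	NA	NA
P72	Deletions only	7	2	72423000	74049001	L2c	AluSz	NA	NA
P2109_302	Deletions only	11	1	89543001	89766001	AT_rich	(TATATG)n	NA	NA
P2109_302	Deletions only	11	2	89640783	91339107	SATR1	HAL1	3	0
P2109_123	Deletions only	17	1	2220421	2617882	AluSx	AluSx1	32	0
P2109_123	Deletions only	17	2	2484970	2649513	AluSq2	AluSq2	NA	NA
P2109_188	Deletions only	21	1	43414906	44797221	THE1B	AluSc	0	52
P2109_188	Deletions only	21	2	44797115	45781411	AluSc	L1MDa	0	46
P2109_188	Deletions only	21	3	45781001	48102000	L1MD2	MLT1I	NA	NA
P81	Deletions only	4	1	154997275	155050347	L2b	MER5A1	0	0
P81	Deletions only	4	2	155164912	171342995	MER81	L1MC2	0	0
P81	Deletions only	4	3	158707726	174401005	L2	L1MC4	4	0
P81	Deletions only	4	4	161297890	166374444	MSTB	T-rich	NA	NA
P2046_133	Deletions only	5	1	389429	154993195	(GGGGA)n	L2a	0	0
P2046_133	Deletions only	5	2	399867	155929947	MIR3	AluJr	3	0
P2046_133	Deletions only	5	3	141466785	143779195	MER117	(TC)n	0	27
P2046_133	Deletions only	5	4	144018754	146087033	L2a	AT_rich	1	0
P2046_133	Deletions only	5	5	146847080	155919592	MLT1A0	L1PA7	1	0
P2046_133	Deletions only	5	6	149533960	157385269	MIRb	AluJr	0	0
P2046_133	Deletions only	5	7	154977468	157385270	MIR	AluJr	0	0
P00	Deletions only	7	1	74942505	77756619	(A)n	(TTTA)n	0	3
P00	Deletions only	7	2	77216339	79914091	Tigger1	(TG)n	0	0
P00	Deletions only	7	3	77226981	77626463	L1MA5	MLT1E1A	1	0
P00	Deletions only	7	4	77313213	78267535	Charlie7a	AluJr	1	0
P00	Deletions only	7	5	77754229	78236952	(TTTA)n	LTR16E1	NA	NA
P00	Deletions only	7	6	77770732	82690202	L2b	MLT1E1	5	0
P00	Deletions only	7	7	78265840	82754314	AluY	SVA_B	2	3
P06	Duplications only	2	1	846167	1855037	MLT1B	MER31B	NA	NA
P06	Duplications only	2	2	1114148	1610546	L1MA7	MLT1K	0	0
P4855_511	Duplications only	2	1	842609	1857566	L1MEg	AT_rich	3	0
P4855_511	Duplications only	2	2	1114148	1610546	L1MA7	MLT1K	0	0
P2109_150	Duplications only	7	1	111281787	114365115	AluSc	L1MA4A	0	NA
P2109_150	Duplications only	7	2	111941768	111963146	L2c	L1M4	2	0
P2109_151	Duplications only	14	1	102138899	104966644	L1M1	L4	3	0
P2109_151	Duplications only	14	2	102589089	105092354	AluSx1	L1MC4a	1	0
P74	Duplications only	16	1	88726889	90023923	AluSz6	MLT1K	NA	NA
P74	Duplications only	16	2	89324612	89772550	L1M4	MIR	NA	NA
P4855_512	Duplications only	21	1	43854243	44846415	MIRb	C-rich	3	0
P4855_512	Duplications only	21	2	44581164	44845646	(CA)n	C-rich	2	0
P4855_512	Duplications only	21	3	44844321	46454415	AluSc8	(TCCTG)n	2	0
P5513_206	Duplications only	14	1	47888602	49718081	AT_rich	L1PA15	0	0
P5513_206	Duplications only	14	2	48264000	61179000	L1MEf	AluY	0	0
P5513_206	Duplications only	14	3	59901890	87383926	L3	L2	1	0
P5513_206	Duplications only	14	4	59922753	64300950	MLT1J	AluSx	0	0
P5513_206	Duplications only	14	5	76522298	87638698	Charlie8	AluSc8	2	0
P2109_162	Deletions and duplications	1	1	238802165	246444835	L1MD3	L2c	3	0
P2109_162	Deletions and duplications	1	2	244149899	246492103	AluJb	L1PA3	2	0
P2109_162	Deletions and duplications	1	3	245599008	247836549	L2a	(CATATA)n	5	0
P2109_162	Deletions and duplications	1	4	246491796	248600189	AT_rich	AT_rich	2	0
P5513_116	Deletions and duplications	X	1	26552817	76868256	L2c	L1MB4	2	0
P5513_116	Deletions and duplications	X	2	77229642	77417095	L1M5	L1PBa1	NA	NA
P5371_204	Deletions and duplications	13	1	93523111	110102355	MIRb	(TA)n	0	8
P5371_204	Deletions and duplications	13	2	110075934	110081348	L3	L3	2	0
P5371_204	Deletions and duplications	13	3	111492499	111980568	L1M4	LTR38B	2	0
P5371_204	Deletions and duplications	13	4	113588473	115000804	MER5A	L1MC4a	2	0
P2109_185	Deletions and duplications	5	1	2559532	2587902	(T)n	MLT1E1A	0	17
P2109_185	Deletions and duplications	5	2	7481754	177636532	L1MA3	MIRb	1	0
P2109_185	Deletions and duplications	5	3	7507896	21097826	MIR	LTR67B	0	1
P2109_185	Deletions and duplications	5	4	7669627	7673762	MER112	MER20	0	12
P2109_176	Deletions and duplications	2	1	186345992	187132941	L2	L1PA7	NA	NA
P2109_176	Deletions and duplications	2	2	186383076	226738875	L1PA8	L1PA2	5	0
P2109_176	Deletions and duplications	2	3	186383301	187298167	L1P3b	HERVL18-int	0	42
P2109_176	Deletions and duplications	2	4	186383200	188892000	L1PA8	L1PB1	NA	NA
P2109_176	Deletions and duplications	2	5	186383235	187133023	L1P3b	L1PA7	NA	NA
P2109_176	Deletions and duplications	2	6	187132942	226652944	L1PA7	AluJr	4	52
P2109_176	Deletions and duplications	2	7	188892330	225311353	L1PB1	L1MEg	3	1
P2109_176	Deletions and duplications	2	8	225311193	226718661	L1MEg	L1PA2	4	0
P1426_301	Deletions and duplications	21	1	17867977	29944106	AT_rich	(TTATA)n	0	2
P1426_301	Deletions and duplications	21	2	27624991	28304789	L2c	AluSg	1	0
P1426_301	Deletions and duplications	21	3	29651577	32467984	MIR	L1PA15	0	8
P1426_301	Deletions and duplications	21	4	29785938	29809107	AluY	(TTTA)n	0	23
P1426_301	Deletions and duplications	21	5	30426349	34185841	AluY	AT_rich	0	14
P1426_301	Deletions and duplications	21	6	30815785	34656669	L1PA2	AluSq	2	0
P1426_301	Deletions and duplications	21	7	34178503	47896585	LTR88a	AluSz	NA	NA
P1426_301	Deletions and duplications	21	8	37539020	46546718	MER1B	MIR3	2	0
P1426_301	Deletions and duplications	21	9	39830239	45423086	AluSg	AT_rich	2	0
P1426_301	Deletions and duplications	21	10	40225591	46563358	MIRb	L2a	3	0
P1426_301	Deletions and duplications	21	11	45504605	47729066	MER21B	AluSx	NA	NA
P1426_301	Deletions and duplications	21	12	28879383	NA	L1MA8	NA	NA	NA
P1426_301	Deletions and duplications	21	13	28316917	NA	L2a	NA	NA	NA
P1426_301	Deletions and duplications	21	14	32678337	NA	L1MC4	NA	NA	NA
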
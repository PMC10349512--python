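SNP	CHR	POS	cFDR.BW	cFDR.NE	ccfdr	gene
rs507288	1	37203702	0.001716	7.49E-09	0.001716	-
rs4660550	1	39688459	0.003108	0.025014	0.025014	MACF1
rs7534143	1	66470379	0.023308	0.034705	0.034705	PDE4B
rs667308	1	155000000	4.87E-11	0.015693	0.015693	DCST2;ZBTB7B
rs3737657	1	204000000	0.012323	0.006953	0.012323	ERLNC1;ETNK2
rs7520276	1	206000000	0.04334	0.02542	0.04334	-
rs2339940	2	24251787	1.56E-07	0.044778	0.044778	WDCP
rs343969	2	44956905	0.034901	0.005843	0.034901	CAMKMT
rs848293	2	58382490	0.01665	0.000111	0.01665	VRK2
rs2863300	2	59188638	0.023732	0.002119	0.023732	LINC01122
rs4419186	2	149000000	0.012493	1.02E-06	0.012493	-
rs6430291	2	149000000	0.02889	4.89E-09	0.02889	MBD5
rs3771300	2	192000000	0.000926	0.040151	0.040151	STAT1
rs9854633	3	4110517	0.040085	0.002747	0.040085	-
rs6795735	3	64705365	0.010544	0.032618	0.032618	ADAMTS9-AS2
rs1861044	4	15539498	0.009337	0.01138	0.01138	CC2D2A
rs4975032	4	39687955	0.042232	0.033192	0.042232	-
rs334195	5	1846721	0.017516	0.023526	0.023526	-
rs2523676	6	31435991	0.01705	0.00036	0.01705	DENND4B;MEN1
rs9267673	6	31883679	0.018701	0.024511	0.024511	C2
rs2734335	6	31893944	0.041245	9.59E-05	0.041245	C2
rs396090	6	32977535	0.043793	0.002408	0.043793	HLA-DOA
rs455567	6	33252115	0.030658	0.0029	0.030658	WDR46
rs6910233	6	33534726	0.026849	0.003178	0.026849	GGNBP1
rs13219530	6	33657493	0.00663	0.009883	0.009883	ITPR3
rs1262557	6	127000000	2.67E-05	0.003099	0.003099	-
rs9492432	6	130000000	0.002543	0.00084	0.002543	-
rs9376653	6	142000000	0.028039	0.010677	0.028039	-
rs1361024	6	152000000	0.002018	0.00958	0.00958	ESR1
rs13225695	7	86702298	0.049035	0.006419	0.049035	-
rs1868757	7	114000000	0.024787	0.029903	0.029903	FOXP2
rs10259338	7	127000000	0.023325	0.002149	0.023325	-
rs1057454	7	127000000	0.001957	0.004818	0.004818	ZNF800
rs10258162	7	127000000	0.0189	0.001356	0.0189	LOC105375490
rs972088	7	127000000	3.57E-05	0.018052	0.018052	SND1
rs6969880	7	127000000	4.58E-05	0.013199	0.013199	SND1
rs10957133	8	61300510	0.018174	0.022692	0.022692	PDCL3P1;LINC01301
rs2737205	8	117000000	0.047282	0.000279	0.047282	TRPS1
rs1147322	9	126000000	5.52E-11	0.021735	0.021735	ZBTB6
rs2540074	9	126000000	1.28E-10	0.044136	0.044136	STRBP
rs2078778	9	137000000	0.021297	0.00786	0.021297	-
rs12344192	9	137000000	0.019154	0.030832	0.030832	-
rs10786706	10	105000000	0.003589	0.002367	0.003589	WBP1L
rs4290163	10	105000000	0.015052	0.01028	0.015052	PCYT2;RPS8;ABCC8;TMEM53;SLC25A32
rs7092200	10	105000000	0.00207	0.001262	0.00207	CNNM2
rs10840346	11	10062999	2.44E-10	0.000621	0.000621	SBF2
rs4430500	11	10254371	3.92E-09	0.000508	0.000508	SBF2
rs3740699	11	47504075	0.046411	0.000109	0.046411	CELF1
rs7939420	11	47723938	0.035053	0.000197	0.035053	AGBL2
rs7117020	11	57499655	0.034854	0.006471	0.034854	TMX2-CTNND1;TMX2
rs4938893	11	58095004	9.41E-05	0.018753	0.018753	-
rs1988657	12	62838595	0.031134	0.049253	0.049253	-
rs1042725	12	66358347	1.27E-54	0.014324	0.014324	HMGA2
rs10161126	12	110000000	0.048314	1.13E-05	0.048314	-
rs11630273	15	40878978	0.039488	0.029126	0.039488	-
rs41434449	15	64448460	0.012405	0.039885	0.039885	PPIB;SNX22
rs35755513	15	64648186	0.006669	7.05E-05	0.006669	CSNK1G1
rs8039305	15	91422543	9.69E-10	0.001754	0.001754	FURIN
rs4075483	17	79074817	0.016128	0.000251	0.016128	BAIAP2
rs1017102	19	56892632	0.021051	0.023505	0.023505	ZNF582;ZNF542P
rs5753037	22	30581722	0.006136	0.009624	0.009624	HORMAD2;LOC105372988
rs4821981	22	41415644	0.044702	8.01E-05	0.044702	AC002378.1
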
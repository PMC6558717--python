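# Published physicochemical properties and scaffold locations of the 35
# B-BOX (BBX) family proteins of Dendrobium officinale (DoBBX01-19) and
# Phalaenopsis equestris (PeBBX01-16), as reported for the two genome
# assemblies.  Coordinates are the printed scaffold positions (3'/5');
# pI is the theoretical isoelectric point, mw_da the molecular weight in Da.
gene	gene_id	scaffold	pos_a	pos_b	pi	mw_da
DoBBX01	Dendrobium_GLEAN_10114110	scaffold1023	110887	111429	5.78	19334.08
DoBBX02	Dendrobium_GLEAN_10103854	scaffold1579	145245	147705	8.4	16408.94
DoBBX03	Dendrobium_GLEAN_10103350	scaffold1615	111626	113154	6.62	49069.17
DoBBX04	Dendrobium_GLEAN_10087464	scaffold2703	47629	52112	8.05	23160.00
DoBBX05	Dendrobium_GLEAN_10083337	scaffold3036	22448	37134	6.38	61659.92
DoBBX06	Dendrobium_GLEAN_10082773	scaffold3055	36993	49949	5.97	47501.90
DoBBX07	Dendrobium_GLEAN_10070006	scaffold4316	51281	52020	6.58	22581.62
DoBBX08	Dendrobium_GLEAN_10066138	scaffold4764	575	5695	5.17	31455.23
DoBBX10	Dendrobium_GLEAN_10059161	scaffold5567	27303	27881	5.89	42498.73
DoBBX09	Dendrobium_GLEAN_10059159	scaffold5567	17687	22526	4.8	40018.87
DoBBX11	Dendrobium_GLEAN_10057235	scaffold5786	5947	12621	5.74	21072.85
DoBBX12	Dendrobium_GLEAN_10061306	scaffold6558	50428	52902	5.9	49066.97
DoBBX13	Dendrobium_GLEAN_10048630	scaffold7094	5715	11039	4.76	29329.54
DoBBX14	Dendrobium_GLEAN_10048191	scaffold7130	45763	46503	6.49	14648.51
DoBBX15	Dendrobium_GLEAN_10030321	scaffold10795	5	481	4.74	15960.99
DoBBX16	Dendrobium_GLEAN_10027946	scaffold11444	5072	6516	5.61	32830.90
DoBBX17	Dendrobium_GLEAN_10027874	scaffold11472	11595	16499	7.48	33074.70
DoBBX18	Dendrobium_GLEAN_10027219	scaffold11757	21929	22994	6.06	30682.53
DoBBX19	Dendrobium_GLEAN_10018021	scaffold15694	2698	3306	5.06	22740.86
PeBBX01	PEQU_00678.1	Scaffold000002	12666119	12668574	6.02	35945.50
PeBBX02	PEQU_00789.1	Scaffold000002	14834552	14844365	5.74	39882.90
PeBBX03	PEQU_20117.1	Scaffold000008	219001	219795	5.13	29606.44
PeBBX04	PEQU_30892.1	Scaffold000028	40165	74304	6.65	23352.53
PeBBX05	PEQU_07418.1	Scaffold000202	1196612	1197568	8.61	35776.22
PeBBX06	PEQU_26523.1	Scaffold000219	340992	368429	6.83	49942.19
PeBBX07	PEQU_04684.1	Scaffold000224	4007418	4008506	6.02	37255.94
PeBBX08	PEQU_07681.1	Scaffold000297	942007	946699	5.5	37633.50
PeBBX09	PEQU_15996.1	Scaffold000411	691452	710139	6.85	47215.68
PeBBX10	PEQU_14525.1	Scaffold000413	746717	747431	7.93	21747.15
PeBBX11	PEQU_32256.1	Scaffold000584	11714	12343	4.35	23138.88
PeBBX12	PEQU_17923.1	Scaffold001081	902228	902798	6.57	18004.64
PeBBX13	PEQU_41941.1	Scaffold001148	10708	12869	5.65	26279.96
PeBBX14	PEQU_41825.1	Scaffold1976	2433	2426	6.68	7492.76
PeBBX15	PEQU_31514.1	Scaffold21087	795748	102447	5.76	20454.13
PeBBX16	PEQU_36421.1	Scaffold233868	116085	131657	5.53	45564.70
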
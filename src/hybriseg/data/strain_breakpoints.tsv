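strain	genome_position	systematic_name	standard_name	orientation	region_start_bp	region_end_bp	chimeric_length_bp	reading_frame	intragenic	uvarum_substitute
DBVPG6033	chrII:780898-780904	YBR289w	SNF5	Sc>Se	1236	1242	2694	Intact	True	False
DBVPG6033	chrIV:1116213-1116246	YDR324c	UTP4	Se>Sc	444	477	2259	Intact	True	False
DBVPG6033	chrVII:179643-179658	YGL173c	KEM1	Se>Sc	462	477	4587	Intact	True	False
DBVPG6033	chrVIII:433729-433738	YHR165c	PRP8	Se>Sc	3222	3231	7251	Intact	True	False
DBVPG6033	chrVIII:451249-451261	Intergenic	Intergenic				NA	NA	False	True
DBVPG6033	chrXIII:843622-843635	YMR287c	MSU1	Se>Sc	1710	1723	2910	Intact	True	False
DBVPG6033	chrXVI:97018-97048	YPL240c	HSP82	Se>Sc	1578	1608	NA	Unknown	True	True
DBVPG6033	chrXVI:482999-483013	YPL036w	PMA2	Se>Sc	121	134	2805	Intact	True	False
DBVPG6033	chrXVI:906846-906880	Intergenic	Intergenic				NA	NA	False	True
DBVPG6261	chrIV:1115814-1115829	YDR324c	UTP4	Se>Sc	861	876	2259	Intact	True	True
DBVPG6261	chrV:507240-507255	YER164w	CHD1	Se>Sc	1848	1863	4401	Intact	True	False
DBVPG6261	chrVII:179643-179658	YGL173c	KEM1	Se>Sc	462	477	4587	Intact	True	False
DBVPG6261	chrXI:60182-60196	YKL203c	TOR2	Sc>Se	3164	3179	7425	Intact	True	False
DBVPG6261	chrXI:285492-285507	YKL080w	VMA5	Sc>Se	819	834	1179	Intact	True	False
DBVPG6261	chrXIII:172148-172154	YML051w	GAL80	Se>Sc	555	561	1308	Intact	True	False
DBVPG6261	chrXIII:882708-882717	YMR306w	FKS3	Se>Sc	1551	1560	5358	Intact	True	False
DBVPG6261	chrXV:496849-496867	YOR092w	ECM3	Sc>Se	1722	1740	1842	Intact	True	False
DBVPG6261	chrXV:526415-526427	YOR109w	INP53	Se>Sc	1137	1149	3324	Intact	True	False
DBVPG6261	chrXV:561420-561425	YOR127w	RGA1	Sc>Se	250	255	3024	Intact	True	False
DBVPG6261	chrXVI:97018-97048	YPL240c	HSP82	Se>Sc	1578	1608	NA	Unknown	True	True
DBVPG6257	chrIV:1148739-1148747	YDR338c	YDR338c	Se>Sc	715	723	2088	Intact	True	False
DBVPG6257	chrVII:179643-179658	YGL173c	KEM1	Se>Sc	462	477	4587	Intact	True	False
DBVPG6257	chrIX:306348-306368	YIL026c	IRR1	Se>Sc	1551	1571	3444	Intact	True	False
DBVPG6257	chrX:453940-453961	YJR009c	TDH2	Se>Sc	714	735	999	Intact	True	True
DBVPG6257	chrXI:354012-354024	YKL045w	PRI2	Sc>Se	877	888	1587	Intact	True	False
DBVPG6257	chrXIII:602992-602998	YMR170c	ALD2	Se>Sc	84	90	1521	Intact	True	True
DBVPG6257	chrXIII:657834-657854	YMR196w	YMR196w	Se>Sc	2790	2811	3297	Intact	True	False
DBVPG6257	chrXVI:97018-97048	YPL240c	HSP82	Se>Sc	1578	1608	NA	Unknown	True	True
DBVPG6257	chrXVI:862750-862765	YPR160w	GPH1	Sc>Se	1449	1464	2709	Intact	True	False
DBVPG6257	chrXVI:919949-919955	YPR191w	QCR2	Se>Sc	574	579	1107	Intact	True	False
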
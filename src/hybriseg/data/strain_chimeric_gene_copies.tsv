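strain	chromosome	systematic_name	standard_name	chimeric	sc	se
DBVPG6033	chrII	YBR289w	SNF5	1	0	1
DBVPG6033	chrIV	YDR324c	UTP4	1	0	1
DBVPG6033	chrVII	YGL173c	KEM1	1	1	1
DBVPG6033	chrVIII	YHR165c	PRP8	1	0	1
DBVPG6033	chrXIII	YMR287c	MSU1	1	0	1
DBVPG6033	chrXVI	YPL240c	HSP82	2	0	0
DBVPG6033	chrXVI	YPL036w	PMA2	1	0	1
DBVPG6261	chrIV	YDR324c	UTP4	1	0	1
DBVPG6261	chrV	YER164w	CHD1	3	0	0
DBVPG6261	chrVII	YGL173c	KEM1	3	0	0
DBVPG6261	chrXI	YKL203c	TOR2	1	0	1
DBVPG6261	chrXI	YKL080w	VMA5	1	0	1
DBVPG6261	chrXIII	YML051w	GAL80	1	0	1
DBVPG6261	chrXIII	YMR306w	FKS3	2	1	0
DBVPG6261	chrXV	YOR092w	ECM3	1	0	1
DBVPG6261	chrXV	YOR109w	INP53	1	0	1
DBVPG6261	chrXV	YOR127w	RGA1	1	0	1
DBVPG6261	chrXVI	YPL240c	HSP82	3	0	0
DBVPG6257	chrIV	YDR338c	YDR338c	2	0	1
DBVPG6257	chrVII	YGL173c	KEM1	1	2	0
DBVPG6257	chrIX	YIL026c	IRR1	3	0	0
DBVPG6257	chrX	YJR009c	TDH2	1	1	1
DBVPG6257	chrXI	YKL045w	PRI2	2	0	2
DBVPG6257	chrXIII	YMR170c	ALD2	1	0	2
DBVPG6257	chrXIII	YMR196w	YMR196w	1	0	2
DBVPG6257	chrXVI	YPL240c	HSP82	3	0	0
DBVPG6257	chrXVI	YPR160w	GPH1	1	0	2
DBVPG6257	chrXVI	YPR191w	QCR2	3	0	0
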
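strain	chromosome	sc_copies	chimeric_copies	se_chromosome	se_copies
DBVPG6033	chrI	1	0	I	0
DBVPG6033	chrII	0	1	II-IV	1
DBVPG6033	chrIII	2	1	III	0
DBVPG6033	chrIV	0	1	IV-II	1
DBVPG6033	chrV	1	0	V	1
DBVPG6033	chrVI	0	0	X-VI	1
DBVPG6033	chrVII	1	1	VII	0
DBVPG6033	chrVIII	0	1	VIII-XV	1
DBVPG6033	chrIX	1	0	IX	1
DBVPG6033	chrX	1	0	VI-X	1
DBVPG6033	chrXI	0	0	XI	2
DBVPG6033	chrXII	0	0	XII	2
DBVPG6033	chrXIII	0	1	XIII	1
DBVPG6033	chrXIV	1	0	XIV	1
DBVPG6033	chrXV	0	1	XV-VIII	1
DBVPG6033	chrXVI	0	2	XVI	0
DBVPG6261	chrI	2	0	I	0
DBVPG6261	chrII	1	0	II-IV	1
DBVPG6261	chrIII	0	0	III	1
DBVPG6261	chrIV	0	1	IV-II	1
DBVPG6261	chrV	0	2	V	0
DBVPG6261	chrVI	0	0	X-VI	1
DBVPG6261	chrVII	0	3	VII	0
DBVPG6261	chrVIII	1	1	VIII-XV	1
DBVPG6261	chrIX	2	0	IX	0
DBVPG6261	chrX	1	0	VI-X	1
DBVPG6261	chrXI	0	1	XI	1
DBVPG6261	chrXII	0	0	XII	2
DBVPG6261	chrXIII	0	2	XIII	0
DBVPG6261	chrXIV	0	0	XIV	1
DBVPG6261	chrXV	0	1	XV-VIII	0
DBVPG6261	chrXVI	0	3	XVI	0
DBVPG6257	chrI	1	0	I	2
DBVPG6257	chrII	2	0	II-IV	1
DBVPG6257	chrIII	2	1	III	0
DBVPG6257	chrIV	0	2	IV-II	1
DBVPG6257	chrV	0	0	V	3
DBVPG6257	chrVI	1	0	X-VI	1
DBVPG6257	chrVII	2	1	VII	0
DBVPG6257	chrVIII	2	0	VIII-XV	1
DBVPG6257	chrIX	0	3	IX	0
DBVPG6257	chrX	1	1	VI-X	1
DBVPG6257	chrXI	0	2	XI	2
DBVPG6257	chrXII	1	0	XII	2
DBVPG6257	chrXIII	0	3	XIII	0
DBVPG6257	chrXIV	2	1	XIV	0
DBVPG6257	chrXV	2	0	XV-VIII	1
DBVPG6257	chrXVI	0	3	XVI	0
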
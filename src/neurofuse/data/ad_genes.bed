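# Editable list of genes with reported Alzheimer's disease associations
# (GRCh37-style coordinates, generous gene-body intervals).
# chrom	start	end	name
1	207660000	207820000	CR1
2	127800000	127870000	BIN1
4	11020000	11120000	HS3ST1
5	88000000	88220000	MEF2C
6	47480000	47520000	CD2AP
8	27450000	27470000	CLU
10	106950000	107020000	SORCS1
10	108740000	108810000	SORCS3
10	50820000	50900000	CHAT
11	85660000	85780000	PICALM
11	121400000	121520000	SORL1
19	44890000	44920000	APOE
19	45340000	45410000	TOMM40
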
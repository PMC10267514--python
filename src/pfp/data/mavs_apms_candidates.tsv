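fl	pr	gene	accession	ppi_databases	virotrap
yes		DDX58	O95786	yes
yes		EIF2AK2	P19525	yes
yes		HLA-C	P10321		yes
yes		HMGCS1	Q01581
yes		IFIT1	P09914	yes	yes
yes		IFIT2	P09913
yes		IFIT3	O14879	yes
yes		ISG15	P05161
yes		KIF2C	Q99661
yes		SLC39A7	Q92504
yes		STAT1	P42224	yes
yes		TPRKB	Q9Y3C4
yes		TRIM25	Q14258	yes
yes		UBA52;RPS27A;UBB;UBC	P62987
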
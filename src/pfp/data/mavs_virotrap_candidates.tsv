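fl	pr	gene	accession	ppi_databases
yes		ACLY	P53396
yes		EEF2	P13639
yes		PKM	P14618
yes		TRAF2	Q12933	yes
yes	yes	ADK	P55263
yes	yes	AHCY	P23526
yes	yes	ASNA1	O43681
yes	yes	ASS1	P00966
yes	yes	BAG6	P46379	yes
yes	yes	BROX	Q5VW32
yes	yes	CHMP1A	Q9HD42
yes	yes	CHMP1B	Q7LBR1
yes	yes	CHMP2A	O43633
yes	yes	CHMP4B	Q9H444
yes	yes	DYNC1H1	Q14204
yes	yes	EPRS	P07814
yes	yes	FERMT3	Q86UX7
yes	yes	FLNA	P21333
yes	yes	GAPDH	P04406
yes	yes	GET4	Q7L5D6
yes	yes	HLA-C	P10321
yes	yes	HSPB1	P04792
yes	yes	HYOU1	Q9Y4L1
yes	yes	IFIT1	P09914	yes
yes	yes	IFNB1	P01574	yes
yes	yes	ILK	Q13418
yes	yes	IST1	P53990
yes	yes	MAPRE2	Q15555
yes	yes	MAVS	Q7Z434
yes	yes	MITD1	Q8WV92
yes	yes	PRPF19	Q9UMS4
yes	yes	RAD23B	P54727
yes	yes	RBBP7	Q16576
yes	yes	SAR1A	Q9NR31
yes	yes	SEPT2	Q15019
yes	yes	SGTA	O43765
yes	yes	TLN1	Q9Y490
yes	yes	UBL4A	P11441
yes	yes	UBQLN1	Q9UMX0
yes	yes	UBQLN4	Q9NRR5
yes	yes	VPS4A	Q9UN37
yes	yes	VTA1	Q9NP79
yes	yes	WDR1	O75083
	yes	ACTL6A	O96019
	yes	CAD	P27708;P31327
	yes	DPYSL2	Q16555
	yes	PGM1	P36871
	yes	PKRKACB	P22694
	yes	PLK1	P53350
	yes	PRKDC	P78527
	yes	PYGL	P06737
	yes	SEPT7	Q16181
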
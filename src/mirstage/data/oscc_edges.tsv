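mirna_id	gene	source_db
hsa-miR-34a-5p	EGFR	stage-tab-hyp
hsa-miR-34a-5p	ERBB2	stage-tab-hyp
hsa-miR-34a-5p	JUN	stage-tab-hyp
hsa-miR-34a-5p	ETS1	stage-tab-hyp
hsa-miR-34a-5p	MYC	stage-tab-hyp
hsa-miR-34a-5p	MKI67	stage-tab-hyp
hsa-miR-34a-5p	TP53	stage-tab-hyp
hsa-miR-34a-5p	CDKN2A	stage-tab-hyp
hsa-miR-124-3p	EGFR	stage-tab-hyp
hsa-miR-124-3p	ERBB2	stage-tab-hyp
hsa-miR-124-3p	JUN	stage-tab-hyp
hsa-miR-124-3p	ETS1	stage-tab-hyp
hsa-miR-124-3p	MYC	stage-tab-hyp
hsa-miR-124-3p	MKI67	stage-tab-hyp
hsa-miR-124-3p	CDKN2A	stage-tab-hyp
hsa-miR-125b-5p	EGFR	stage-tab-hyp
hsa-miR-125b-5p	ERBB2	stage-tab-hyp
hsa-miR-125b-5p	JUN	stage-tab-hyp
hsa-miR-125b-5p	ETS1	stage-tab-hyp
hsa-miR-125b-5p	MKI67	stage-tab-hyp
hsa-miR-125b-5p	TP53	stage-tab-hyp
hsa-miR-125b-5p	CDKN2A	stage-tab-hyp
hsa-miR-34a-5p	EGFR	stage-tab-dys
hsa-miR-34a-5p	ERBB2	stage-tab-dys
hsa-miR-34a-5p	FGFR2	stage-tab-dys
hsa-miR-34a-5p	FGFR3	stage-tab-dys
hsa-miR-34a-5p	ETS1	stage-tab-dys
hsa-miR-34a-5p	MYC	stage-tab-dys
hsa-miR-34a-5p	JUN	stage-tab-dys
hsa-miR-34a-5p	TP53	stage-tab-dys
hsa-miR-34a-5p	MKI67	stage-tab-dys
hsa-miR-124-3p	EGFR	stage-tab-dys
hsa-miR-124-3p	ERBB2	stage-tab-dys
hsa-miR-124-3p	FGFR3	stage-tab-dys
hsa-miR-124-3p	ETS1	stage-tab-dys
hsa-miR-124-3p	MYC	stage-tab-dys
hsa-miR-124-3p	JUN	stage-tab-dys
hsa-miR-124-3p	MKI67	stage-tab-dys
hsa-miR-125b-5p	EGFR	stage-tab-dys
hsa-miR-125b-5p	ERBB2	stage-tab-dys
hsa-miR-125b-5p	FGFR2	stage-tab-dys
hsa-miR-125b-5p	ETS1	stage-tab-dys
hsa-miR-125b-5p	JUN	stage-tab-dys
hsa-miR-125b-5p	TP53	stage-tab-dys
hsa-miR-125b-5p	MKI67	stage-tab-dys
hsa-miR-1-3p	EGFR	stage-tab-dys
hsa-miR-1-3p	FGFR2	stage-tab-dys
hsa-miR-1-3p	ETS1	stage-tab-dys
hsa-miR-1-3p	MYC	stage-tab-dys
hsa-miR-1-3p	JUN	stage-tab-dys
hsa-miR-1-3p	TP53	stage-tab-dys
hsa-miR-1-3p	MKI67	stage-tab-dys
hsa-miR-34a-5p	EGFR	stage-tab-inv
hsa-miR-34a-5p	FGFR2	stage-tab-inv
hsa-miR-34a-5p	FGFR3	stage-tab-inv
hsa-miR-34a-5p	ETS1	stage-tab-inv
hsa-miR-34a-5p	JUN	stage-tab-inv
hsa-miR-34a-5p	CDKN2A	stage-tab-inv
hsa-miR-34a-5p	BCL2	stage-tab-inv
hsa-miR-124-3p	EGFR	stage-tab-inv
hsa-miR-124-3p	FGFR3	stage-tab-inv
hsa-miR-124-3p	ETS1	stage-tab-inv
hsa-miR-124-3p	JUN	stage-tab-inv
hsa-miR-125b-5p	EGFR	stage-tab-inv
hsa-miR-125b-5p	FGFR2	stage-tab-inv
hsa-miR-125b-5p	ETS1	stage-tab-inv
hsa-miR-125b-5p	JUN	stage-tab-inv
hsa-miR-1-3p	EGFR	stage-tab-inv
hsa-miR-1-3p	FGFR2	stage-tab-inv
hsa-miR-1-3p	ETS1	stage-tab-inv
hsa-miR-1-3p	JUN	stage-tab-inv
hsa-miR-147a	EGFR	stage-tab-inv
hsa-miR-147a	FGFR2	stage-tab-inv
hsa-miR-147a	ETS1	stage-tab-inv
hsa-miR-147a	JUN	stage-tab-inv
hsa-miR-155-5p	CDKN2A	stage-tab-inv
hsa-miR-155-5p	BCL2	stage-tab-inv
hsa-miR-423-3p	CDKN2A	stage-tab-inv
hsa-miR-423-3p	BCL2	stage-tab-inv
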
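mirna_id	direction	source	reference
hsa-miR-34a-5p	down	tissue	oscc-lit-db
hsa-miR-34a-5p	down	saliva	oscc-lit-db
hsa-miR-34a-5p	up	saliva	oscc-lit-db
hsa-miR-124-3p	down	tissue	oscc-lit-db
hsa-miR-124-3p	down	saliva	oscc-lit-db
hsa-miR-125b-5p	down	tissue	oscc-lit-db
hsa-miR-1-3p	down	tissue	oscc-lit-db
hsa-miR-147a	down	saliva	oscc-lit-db
hsa-miR-155-5p	up	tissue	oscc-lit-db
hsa-miR-155-5p	up	saliva	oscc-lit-db
hsa-miR-423-3p	up	tissue	oscc-lit-db
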
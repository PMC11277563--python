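mirna_id	direction	source	reference
miR-1307-5p	up	saliva_exosome	oscc-lit-2024-a
miR-193b-3p	up	saliva	oscc-lit-2024-a
miR-19a-3p	up	tissue	oscc-lit-2024-b
miR-200c-3p	up	tissue	oscc-lit-2024-c
miR-200c-3p	up	cell_line	oscc-lit-2024-c
miR-23a-3p	up	tissue	oscc-lit-2024-c
miR-23a-3p	up	cell_line	oscc-lit-2024-c
miR-345-5p	up	tissue	oscc-lit-2024-a
miR-345-5p	up	saliva	oscc-lit-2024-d
miR-378a	up	tissue	oscc-lit-2024-c
miR-378a	up	cell_line	oscc-lit-2024-c
let-7g-5p	down	tissue	oscc-lit-2024-b
miR-133b	down	tissue	oscc-lit-2024-d
miR-140-5p	down	saliva_exosome	oscc-lit-2024-a
miR-143-5p	down	saliva_exosome	oscc-lit-2024-a
miR-15a-5p	down	saliva	oscc-lit-2024-a
miR-16-1-3p	down	saliva	oscc-lit-2024-a
miR-30c-5p	down	saliva	oscc-lit-2024-a
miR-363-3p	down	tissue	oscc-lit-2024-b
miR-3928	down	saliva	oscc-lit-2024-a
miR-424-3p	down	saliva	oscc-lit-2024-a
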
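- stage: hyperplasia
  direction: up
  genes: [EGFR, ERBB2, JUN, ETS1, MYC, MKI67, CDKN2A, TP53]
- stage: dysplasia
  direction: up
  genes: [EGFR, ERBB2, FGFR2, FGFR3, ETS1, JUN, MYC, MKI67, TP53]
- stage: dysplasia
  direction: down
  genes: [CDKN2A, NRAS, BCL2]
- stage: early_invasion
  direction: up
  genes: [EGFR, FGFR2, FGFR3, ETS1, JUN]
- stage: early_invasion
  direction: down
  genes: [CDKN2A, BCL2]
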
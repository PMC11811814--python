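# Marker gene config for B-lineage subset gating.
#
# Generic literature-style mouse B-cell markers, shipped as an editable
# starting point only — replace with the marker tables of your own study.
# Every subset needs at least one marker; scores are the mean log2FC over
# the listed genes.

subsets:
  immature_b: [CD93, VPREB3, MS4A1]
  naive_b: [IGHD, FCER2A, SELL]
  activated_b: [CD69, CD86, NR4A1]
  gcbc: [AICDA, BCL6, GCSAM]
  mbc: [CCR6, ZEB2, CD80]
  plasma_cell: [PRDM1, XBP1, SDC1]

gc_zones:
  gc_dz: [CXCR4, MKI67, TOP2A]
  gc_lz: [CD83, CXCR5, BCL2A1]

pc_states:
  plasmablast: [MKI67, CCND2, CD28]
  immature_pc: [TIGIT, CXCR3, ITGB7]
  mature_pc: [SLAMF7, TNFRSF17, ENO1]
  apoptotic_pc: [BAX, CASP3, BCL2L11]
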
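# Pathway gene sets for modulation scoring.
#
# Static, editable config: glycolysis runs from glucose uptake to
# pyruvate, lactate metabolism covers the pyruvate -> lactate step, and
# the TCA cycle starts at acetyl-CoA formation; the remaining sets are
# KEGG-style selections. Replace with the gene sets of your own study —
# no database is queried at runtime.

glycolysis: [HK1, HK2, GPI1, PFKL, PFKM, ALDOA, TPI1, GAPDH, PGK1, PGAM1, ENO1, PKM]
lactate_metabolism: [LDHA, LDHB, SLC16A1, SLC16A3]
tca_cycle: [CS, ACO2, IDH2, IDH3A, OGDH, SUCLA2, SDHA, FH1, MDH2]
ppp: [G6PDX, PGLS, PGD, TKT, TALDO1, RPIA]
oxphos: [NDUFA1, NDUFB5, SDHB, UQCRC1, COX5A, COX7B, ATP5A1, ATP5B]
fa_synthesis: [ACACA, FASN, SCD1, ELOVL6]
fao: [CPT1A, CPT2, ACADM, ACADL, HADHA, ECHS1]
glutaminolysis: [GLS, GLUD1, GOT1, GOT2, SLC1A5]
bcr_signaling: [CD79A, CD79B, SYK, BTK, BLNK, PLCG2, PIK3CD, CARD11, NFKB1]
tlr4_signaling: [TLR4, CD14, LY96, MYD88, IRAK4, TRAF6, TICAM1, NFKB1, MAPK14]
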
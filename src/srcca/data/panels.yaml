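# Default marker panels and alias table for hPSC-derived retinal cultures.
#
# Aliases map protein/common names used in the literature to the gene
# symbols expected in expression matrices.  "CB2" here denotes CALB2
# (calretinin/calbindin-2); the common name is ambiguous in the
# literature, so override the alias if your annotation differs.
# The negative panels are editable defaults, not an authoritative list.
aliases:
  BRN3: [POU4F1, POU4F2, POU4F3]
  BRN3A: POU4F1
  BRN3B: POU4F2
  BRN3C: POU4F3
  CART: CARTPT
  MELANOPSIN: OPN4
  PARVALBUMIN: PVALB
  JAM-B: JAM2
  CB2: CALB2

panels:
  - name: pan_rgc_targets
    role: pan_rgc_targets
    genes: [BRN3B, ISL1, SNCG, RBPMS]
  - name: ds_targets
    role: pan_rgc_targets
    genes: [FSTL4, BRN3B, SNCG]
  - name: on_off_ds
    role: subtype_panel
    genes: [CART, CDH6]
  - name: on_ds
    role: subtype_panel
    genes: [FSTL4]
  - name: alpha
    role: subtype_panel
    genes: [SPP1, KCNG4, CB2]
  - name: iprgc
    role: subtype_panel
    genes: [MELANOPSIN]
  - name: pv
    role: subtype_panel
    genes: [PARVALBUMIN]
  - name: w3b
    role: subtype_panel
    genes: [SDK2]
  - name: j
    role: subtype_panel
    genes: [JAM-B]
  - name: progenitor
    role: negative_panel
    genes: [VSX2, LHX2, PAX6, SIX6]
  - name: rpe
    role: negative_panel
    genes: [MITF, RPE65, PMEL, TYR]
  - name: photoreceptor
    role: negative_panel
    genes: [CRX, RCVRN, NRL, OTX2]
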
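# Default drug rulebook for the six-agent targeted-therapy panel.
# DNA-actionable rules take priority over expression evidence.
# Doses are the pediatric doses used with this panel (informational only).
panel:
  bortezomib:
    dose: ""
  crizotinib:
    dose: "165 mg/m2/dose oral twice daily"
  dasatinib:
    dose: "60 mg/m2/dose oral daily"
  lapatinib:
    dose: ""
  sorafenib:
    dose: "150 mg/m2/dose oral twice daily"
  vorinostat:
    dose: "230 mg/m2/dose oral daily"
dna_rules:
  - {drug: crizotinib, gene: ALK, kind: SNV}
  - {drug: crizotinib, gene: ALK, kind: CN-gain}
  - {drug: crizotinib, gene: ALK, kind: fusion}
expression_rules:
  vorinostat: [HDAC2, HDAC4, HDAC8, HDAC9, CTBP2, RAD23]
  crizotinib: [ALK]
  sorafenib: [RET, KIT, PDGFRA, BRAF]
  dasatinib: [PDGFRB, DDR2, SRC, LCK]
# Genes used by the tumor board as contextual evidence rather than canonical
# direct drug targets.
contextual_evidence: [CTBP2, RAD23]
tie_break: alphabetical
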
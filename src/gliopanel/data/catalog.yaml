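# Default RNA-event catalog: fusions (and variant transcripts) with known CNS
# context and candidate targeted therapies.  Partner order is not meaningful;
# lookups sort partners and normalize event names case-insensitively.
#
# bbb_penetrant flags whether the drug crosses the blood-brain barrier; among
# the default entries only crizotinib does not.
version: 1
fusions:
  - name: EGFRvIII
    partners: [EGFR, EGFR]
    context: "IDH-wildtype glioblastoma (variant transcript, deletion of exons 2-7)"
    therapies: []
  - name: BRAF-KIAA1549
    partners: [BRAF, KIAA1549]
    context: "pilocytic astrocytoma"
    therapies: []
  - name: FGFR3-TACC3
    partners: [FGFR3, TACC3]
    context: "IDH-wildtype infiltrating astrocytoma"
    therapies: []
  - name: FGFR1-TACC1
    partners: [FGFR1, TACC1]
    context: "IDH-wildtype infiltrating astrocytoma"
    therapies: []
  - name: MET-PTPRZ1
    partners: [MET, PTPRZ1]
    context: "IDH-mutant high-grade astrocytoma"
    therapies:
      - {drug: "MET kinase inhibitors (investigational)", bbb_penetrant: true}
  - name: NTRK2-ETV6
    partners: [NTRK2, ETV6]
    context: "IDH-mutant infiltrating astrocytoma"
    therapies:
      - {drug: larotrectinib, bbb_penetrant: true}
      - {drug: entrectinib, bbb_penetrant: true}
  - name: GOPC-ROS1
    partners: [GOPC, ROS1]
    context: "IDH-wildtype infiltrating astrocytoma"
    therapies:
      - {drug: crizotinib, bbb_penetrant: false}
      - {drug: lorlatinib, bbb_penetrant: true}
  - name: RET-CCDC6
    partners: [RET, CCDC6]
    context: "IDH-wildtype infiltrating astrocytoma"
    therapies:
      - {drug: cabozantinib, bbb_penetrant: true}
      - {drug: vandetanib, bbb_penetrant: true}
  - name: RET-PCM1
    partners: [RET, PCM1]
    context: "IDH-wildtype infiltrating astrocytoma"
    therapies:
      - {drug: cabozantinib, bbb_penetrant: true}
      - {drug: vandetanib, bbb_penetrant: true}
  - name: PDGFRA-SCAF11
    partners: [PDGFRA, SCAF11]
    context: "IDH-wildtype infiltrating astrocytoma"
    novel_in_cns: true
    therapies: []
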
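# Default gene-arm assignment for the targeted panel.
#
# The 1p/1q/19p/19q groups are fixed by the assay design; the chromosome-7
# background (genes other than EGFR used as the denominator of the EGFR
# copy-number ratio), the chromosome-10 set (for the +7/-10 molecular
# glioblastoma criterion), and the optional chr9p set (for broad-9p loss
# around CDKN2A) are laboratory-configurable.
genes:
  MTOR:    {chromosome: "1",  arm: p}
  MYCL:    {chromosome: "1",  arm: p}
  MPL:     {chromosome: "1",  arm: p}
  MAGOH:   {chromosome: "1",  arm: p}
  JAK1:    {chromosome: "1",  arm: p}
  NRAS:    {chromosome: "1",  arm: p}
  BCL9:    {chromosome: "1",  arm: q}
  MCL1:    {chromosome: "1",  arm: q}
  DDR2:    {chromosome: "1",  arm: q}
  MDM4:    {chromosome: "1",  arm: q}
  STK11:   {chromosome: "19", arm: p}
  GNA11:   {chromosome: "19", arm: p}
  MAP2K2:  {chromosome: "19", arm: p}
  JAK3:    {chromosome: "19", arm: p}
  CCNE1:   {chromosome: "19", arm: q}
  PPP2R1A: {chromosome: "19", arm: q}
  EGFR:    {chromosome: "7",  arm: p}
  BRAF:    {chromosome: "7",  arm: q}
  CDK6:    {chromosome: "7",  arm: q}
  MET:     {chromosome: "7",  arm: q}
  SMO:     {chromosome: "7",  arm: q}
  PTEN:    {chromosome: "10", arm: q}
  FGFR2:   {chromosome: "10", arm: q}
  GATA3:   {chromosome: "10", arm: p}
  CDKN2A:  {chromosome: "9",  arm: p}
  JAK2:    {chromosome: "9",  arm: p}

arm_sets:
  arm_1p:          [MTOR, MYCL, MPL, MAGOH, JAK1, NRAS]
  arm_1q:          [BCL9, MCL1, DDR2, MDM4]
  arm_19p:         [STK11, GNA11, MAP2K2, JAK3]
  arm_19q:         [CCNE1, PPP2R1A]
  chr7_background: [BRAF, CDK6, MET, SMO]
  chr10_set:       [PTEN, FGFR2, GATA3]
  chr9p_set:       [JAK2]
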
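# Default 32-gene myeloid driver panel used by the classifier, with the 11
# secondary-AML-like (sAML) class-defining features flagged.  MLL-PTD (the
# KMT2A partial tandem duplication) is represented as gene MLL with mutation
# consequence "ptd".
genes:
  - ASXL1
  - BCOR
  - CBL
  - CEBPA
  - CSF3R
  - DNMT3A
  - ETV6
  - EZH2
  - FLT3
  - GATA2
  - IDH1
  - IDH2
  - JAK2
  - KIT
  - KRAS
  - MLL
  - NF1
  - NPM1
  - NRAS
  - PHF6
  - PTPN11
  - RAD21
  - RUNX1
  - SETBP1
  - SF3B1
  - SRSF2
  - STAG2
  - TET2
  - TP53
  - U2AF1
  - WT1
  - ZRSR2
saml_class_defining:
  - SRSF2
  - SF3B1
  - U2AF1
  - ZRSR2
  - ASXL1
  - EZH2
  - BCOR
  - STAG2
  - RUNX1
  - SETBP1
  - MLL-PTD
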
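# Default exclusion term lists for safety screening of candidate strains.
# Category names are fixed; terms are matched case-insensitively as product
# substrings or exactly against term ids.
transferable_AMR:
  - vanA
  - vanB
  - vancomycin resistance
  - tetM
  - tet(M)
  - ermB
  - blaCTX
  - mecA
  - aminoglycoside acetyltransferase
virulence_factor:
  - shiga toxin
  - stx1
  - stx2
  - enterotoxin
  - fragilysin
  - hemolysin
  - intimin
  - invasin
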
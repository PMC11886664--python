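# Mulliken charges, DSD-BLYP/Sappo-TZP/DZP, cisplatin gas phase
# columns: atom_index charge (e)
  1  0.11478
  2  -0.39988
  3  -0.40007
  4  -0.06204
  5  -0.06219
  6  0.12794
  7  0.14823
  8  0.14832
  9  0.12844
 10  0.12841
 11  0.12806
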
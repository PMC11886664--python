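# CHELPG charges, DSD-BLYP/Sappo-TZP/DZP, cisplatin gas phase
# columns: atom_index charge (e)
  1  -0.02521
  2  -0.33530
  3  -0.33671
  4  -0.39325
  5  -0.40119
  6  0.26015
  7  0.22269
  8  0.22688
  9  0.26098
 10  0.25938
 11  0.26158
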
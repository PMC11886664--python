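# Hirshfeld charges, DSD-BLYP/Sappo-TZP/DZP, cisplatin gas phase
# columns: atom_index charge (e)
  1  -0.04782
  2  -0.28769
  3  -0.28809
  4  -0.09487
  5  -0.09475
  6  0.14114
  7  0.12395
  8  0.12423
  9  0.14136
 10  0.14135
 11  0.14120
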
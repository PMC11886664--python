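# Mulliken charges, periodic PBE-D3, alpha-cisplatin solid (unit cell)
# columns: atom_index charge (e)
  1  0.19
  2  0.19
  3  -0.31
  4  -0.31
  5  -0.34
  6  -0.34
  7  -0.81
  8  -0.81
  9  -0.83
 10  -0.83
 11  0.34
 12  0.34
 13  0.34
 14  0.34
 15  0.35
 16  0.35
 17  0.36
 18  0.36
 19  0.34
 20  0.34
 21  0.36
 22  0.36
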
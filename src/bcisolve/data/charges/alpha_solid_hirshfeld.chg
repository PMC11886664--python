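# Hirshfeld charges, periodic PBE-D3, alpha-cisplatin solid (unit cell)
# columns: atom_index charge (e)
  1  0.10
  2  0.10
  3  -0.14
  4  -0.14
  5  -0.15
  6  -0.15
  7  -0.16
  8  -0.16
  9  -0.15
 10  -0.15
 11  0.08
 12  0.08
 13  0.08
 14  0.08
 15  0.08
 16  0.08
 17  0.08
 18  0.08
 19  0.08
 20  0.08
 21  0.09
 22  0.09
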
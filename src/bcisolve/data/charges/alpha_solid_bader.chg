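# Bader (AIM) charges, periodic PBE-D3, alpha-cisplatin solid (unit cell)
# columns: atom_index charge (e)
  1  0.54
  2  0.54
  3  -0.54
  4  -0.54
  5  -0.54
  6  -0.54
  7  -1.19
  8  -1.19
  9  -1.21
 10  -1.21
 11  0.49
 12  0.49
 13  0.49
 14  0.49
 15  0.48
 16  0.48
 17  0.50
 18  0.50
 19  0.51
 20  0.51
 21  0.46
 22  0.46
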
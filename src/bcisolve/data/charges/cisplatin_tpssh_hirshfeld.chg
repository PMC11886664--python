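# Hirshfeld charges, TPSSh/DKH-TZVP/TZVP, cisplatin gas phase
# columns: atom_index charge (e)
  1  -0.01809
  2  -0.28467
  3  -0.28471
  4  -0.10053
  5  -0.10052
  6  0.13898
  7  0.11606
  8  0.11607
  9  0.13919
 10  0.13921
 11  0.13901
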
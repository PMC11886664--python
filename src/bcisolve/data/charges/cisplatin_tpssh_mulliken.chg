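# Mulliken charges, TPSSh/DKH-TZVP/TZVP, cisplatin gas phase
# columns: atom_index charge (e)
  1  0.33260
  2  -0.41383
  3  -0.41381
  4  -0.54101
  5  -0.54098
  6  0.26306
  7  0.26109
  8  0.26109
  9  0.26423
 10  0.26435
 11  0.26320
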
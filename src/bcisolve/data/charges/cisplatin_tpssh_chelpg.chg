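# CHELPG charges, TPSSh/DKH-TZVP/TZVP, cisplatin gas phase
# columns: atom_index charge (e)
  1  -0.01859
  2  -0.31571
  3  -0.31917
  4  -0.42569
  5  -0.42924
  6  0.26935
  7  0.21318
  8  0.21666
  9  0.26946
 10  0.26952
 11  0.27023
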
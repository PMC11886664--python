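# Hirshfeld charges, PBE-QIDH/DKH-TZVPP/TZVP, [PtCl4]2- gas phase
# columns: atom_index charge (e)
  1  -0.16918
  2  -0.45771
  3  -0.45771
  4  -0.45771
  5  -0.45770
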
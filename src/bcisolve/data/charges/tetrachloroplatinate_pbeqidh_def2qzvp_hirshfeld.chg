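# Hirshfeld charges, PBE-QIDH/def2-QZVP, [PtCl4]2- gas phase
# columns: atom_index charge (e)
  1  -0.15493
  2  -0.46117
  3  -0.46129
  4  -0.46117
  5  -0.46144
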
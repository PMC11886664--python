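# Mulliken charges, PBE-QIDH/def2-QZVP, [PtCl4]2- gas phase
# columns: atom_index charge (e)
  1  0.85077
  2  -0.71269
  3  -0.71269
  4  -0.71270
  5  -0.71269
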
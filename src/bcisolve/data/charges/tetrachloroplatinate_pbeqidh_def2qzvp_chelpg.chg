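# CHELPG charges, PBE-QIDH/def2-QZVP, [PtCl4]2- gas phase
# columns: atom_index charge (e)
  1  0.44168
  2  -0.60937
  3  -0.61090
  4  -0.61038
  5  -0.61102
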
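# Mulliken charges, PBE-QIDH/DKH-TZVPP/TZVP, [PtCl4]2- gas phase
# columns: atom_index charge (e)
  1  0.28027
  2  -0.57007
  3  -0.57007
  4  -0.57007
  5  -0.57007
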
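# CHELPG charges, PBE-QIDH/DKH-TZVPP/TZVP, [PtCl4]2- gas phase
# columns: atom_index charge (e)
  1  0.29999
  2  -0.57397
  3  -0.57527
  4  -0.57510
  5  -0.57566
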
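@<TRIPOS>MOLECULE
tetrachloroplatinate(II)
    5     4 0 0 0
SMALL
NO_CHARGES
@<TRIPOS>ATOM
      1 Pt1          0.0000     0.0000     0.0000 Pt       1 RES1     0.000000
      2 Cl2          0.0000     0.0000     0.0000 Cl       1 RES1     0.000000
      3 Cl3          0.0000     0.0000     0.0000 Cl       1 RES1     0.000000
      4 Cl4          0.0000     0.0000     0.0000 Cl       1 RES1     0.000000
      5 Cl5          0.0000     0.0000     0.0000 Cl       1 RES1     0.000000
@<TRIPOS>BOND
     1      1      2 1
     2      1      3 1
     3      1      4 1
     4      1      5 1
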
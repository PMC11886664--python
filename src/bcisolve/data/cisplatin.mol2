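@<TRIPOS>MOLECULE
cisplatin
   11    10 0 0 0
SMALL
NO_CHARGES
@<TRIPOS>ATOM
      1 Pt1          0.0000     0.0000     0.0000 Pt       1 RES1     0.000000
      2 Cl2          0.0000     0.0000     0.0000 Cl       1 RES1     0.000000
      3 Cl3          0.0000     0.0000     0.0000 Cl       1 RES1     0.000000
      4 N4           0.0000     0.0000     0.0000 N        1 RES1     0.000000
      5 N5           0.0000     0.0000     0.0000 N        1 RES1     0.000000
      6 H6           0.0000     0.0000     0.0000 H        1 RES1     0.000000
      7 H7           0.0000     0.0000     0.0000 H        1 RES1     0.000000
      8 H8           0.0000     0.0000     0.0000 H        1 RES1     0.000000
      9 H9           0.0000     0.0000     0.0000 H        1 RES1     0.000000
     10 H10          0.0000     0.0000     0.0000 H        1 RES1     0.000000
     11 H11          0.0000     0.0000     0.0000 H        1 RES1     0.000000
@<TRIPOS>BOND
     1      1      2 1
     2      1      3 1
     3      1      4 1
     4      1      5 1
     5      4      6 1
     6      4      7 1
     7      4      8 1
     8      5      9 1
     9      5     10 1
    10      5     11 1
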
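@<TRIPOS>MOLECULE
tetraammineplatinum(II)
   17    16 0 0 0
SMALL
NO_CHARGES
@<TRIPOS>ATOM
      1 Pt1          0.0000     0.0000     0.0000 Pt       1 RES1     0.000000
      2 N2           0.0000     0.0000     0.0000 N        1 RES1     0.000000
      3 N3           0.0000     0.0000     0.0000 N        1 RES1     0.000000
      4 N4           0.0000     0.0000     0.0000 N        1 RES1     0.000000
      5 N5           0.0000     0.0000     0.0000 N        1 RES1     0.000000
      6 H6           0.0000     0.0000     0.0000 H        1 RES1     0.000000
      7 H7           0.0000     0.0000     0.0000 H        1 RES1     0.000000
      8 H8           0.0000     0.0000     0.0000 H        1 RES1     0.000000
      9 H9           0.0000     0.0000     0.0000 H        1 RES1     0.000000
     10 H10          0.0000     0.0000     0.0000 H        1 RES1     0.000000
     11 H11          0.0000     0.0000     0.0000 H        1 RES1     0.000000
     12 H12          0.0000     0.0000     0.0000 H        1 RES1     0.000000
     13 H13          0.0000     0.0000     0.0000 H        1 RES1     0.000000
     14 H14          0.0000     0.0000     0.0000 H        1 RES1     0.000000
     15 H15          0.0000     0.0000     0.0000 H        1 RES1     0.000000
     16 H16          0.0000     0.0000     0.0000 H        1 RES1     0.000000
     17 H17          0.0000     0.0000     0.0000 H        1 RES1     0.000000
@<TRIPOS>BOND
     1      1      2 1
     2      1      3 1
     3      1      4 1
     4      1      5 1
     5      2      6 1
     6      2      7 1
     7      2      8 1
     8      3      9 1
     9      3     10 1
    10      3     11 1
    11      4     12 1
    12      4     13 1
    13      4     14 1
    14      5     15 1
    15      5     16 1
    16      5     17 1
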
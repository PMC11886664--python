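@<TRIPOS>MOLECULE
alpha-cisplatin-unit-cell
   22    20 0 0 0
SMALL
NO_CHARGES
@<TRIPOS>ATOM
      1 Pt1          0.0000     0.0000     0.0000 Pt       1 RES1     0.000000
      2 Pt2          0.0000     0.0000     0.0000 Pt       1 RES1     0.000000
      3 Cl3          0.0000     0.0000     0.0000 Cl       1 RES1     0.000000
      4 Cl4          0.0000     0.0000     0.0000 Cl       1 RES1     0.000000
      5 Cl5          0.0000     0.0000     0.0000 Cl       1 RES1     0.000000
      6 Cl6          0.0000     0.0000     0.0000 Cl       1 RES1     0.000000
      7 N7           0.0000     0.0000     0.0000 N        1 RES1     0.000000
      8 N8           0.0000     0.0000     0.0000 N        1 RES1     0.000000
      9 N9           0.0000     0.0000     0.0000 N        1 RES1     0.000000
     10 N10          0.0000     0.0000     0.0000 N        1 RES1     0.000000
     11 H11          0.0000     0.0000     0.0000 H        1 RES1     0.000000
     12 H12          0.0000     0.0000     0.0000 H        1 RES1     0.000000
     13 H13          0.0000     0.0000     0.0000 H        1 RES1     0.000000
     14 H14          0.0000     0.0000     0.0000 H        1 RES1     0.000000
     15 H15          0.0000     0.0000     0.0000 H        1 RES1     0.000000
     16 H16          0.0000     0.0000     0.0000 H        1 RES1     0.000000
     17 H17          0.0000     0.0000     0.0000 H        1 RES1     0.000000
     18 H18          0.0000     0.0000     0.0000 H        1 RES1     0.000000
     19 H19          0.0000     0.0000     0.0000 H        1 RES1     0.000000
     20 H20          0.0000     0.0000     0.0000 H        1 RES1     0.000000
     21 H21          0.0000     0.0000     0.0000 H        1 RES1     0.000000
     22 H22          0.0000     0.0000     0.0000 H        1 RES1     0.000000
@<TRIPOS>BOND
     1      1      3 1
     2      1      5 1
     3      1      7 1
     4      1      9 1
     5      2      4 1
     6      2      6 1
     7      2      8 1
     8      2     10 1
     9      7     11 1
    10      7     12 1
    11      7     13 1
    12      8     14 1
    13      8     15 1
    14      8     16 1
    15      9     17 1
    16      9     18 1
    17      9     19 1
    18     10     20 1
    19     10     21 1
    20     10     22 1
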
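diazepam
  molpat

 20 22  0  0  0  0  0  0  0  0999 V2000
    3.1476   -2.1380    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.6852   -2.4718    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
    0.7500   -1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7500    1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7500    1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.5000    2.5981    0.0000 Cl  0  0  0  0  0  0  0  0  0  0  0  0
   -1.5000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7500   -1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.6852   -2.4718    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.3515   -3.9342    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
   -0.0000   -4.5850    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.3515   -3.9342    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.5242   -4.8694    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
   -3.1476   -2.1380    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.5898   -0.7046    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -5.0522   -0.3709    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -6.0724   -1.4704    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -5.6303   -2.9038    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -4.1679   -3.2376    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  3  4  2  0
  4  5  1  0
  5  6  2  0
  6  7  1  0
  6  8  1  0
  8  9  2  0
  9 10  1  0
 10 11  2  0
 11 12  1  0
 12 13  1  0
 13 14  2  0
 10 15  1  0
 15 16  2  0
 16 17  1  0
 17 18  2  0
 18 19  1  0
 19 20  2  0
 13  2  1  0
 20 15  1  0
  9  3  1  0
M  END
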
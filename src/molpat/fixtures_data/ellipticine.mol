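ellipticine
  molpat

 19 22  0  0  0  0  0  0  0  0999 V2000
    3.0000   -2.5981    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5000   -2.5981    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7500   -1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7500    1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7500    1.2990    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
   -1.5000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7500   -1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.5000   -2.5981    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.0000   -2.5981    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7500   -3.8971    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7500   -3.8971    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.2135   -5.3237    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000   -6.2054    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.1568   -7.6972    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.5271   -8.3073    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.7406   -7.4256    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.5838   -5.9338    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.2135   -5.3237    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  2  0
  3  4  1  0
  4  5  2  0
  5  6  1  0
  6  7  2  0
  7  8  1  0
  8  9  2  0
  9 10  1  0
  9 11  1  0
 11 12  2  0
 12 13  1  0
 13 14  1  0
 14 15  2  0
 15 16  1  0
 16 17  2  0
 17 18  1  0
 18 19  2  0
 12  2  1  0
 19 14  1  0
  8  3  1  0
 19 11  1  0
M  END
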
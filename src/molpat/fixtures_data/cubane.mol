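cubane
  molpat

  8 12  0  0  0  0  0  0  0  0999 V2000
    1.0607    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.0000   -1.0607    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.0607    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    1.0607    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.0607    2.1213    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.1213    1.0607    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.0607   -2.1213    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.1213   -1.0607    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  3  4  1  0
  4  5  1  0
  5  6  1  0
  6  7  1  0
  7  8  1  0
  4  1  1  0
  6  1  1  0
  7  2  1  0
  8  3  1  0
  8  5  1  0
M  END
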
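tropylium
  molpat

  7  7  0  0  0  0  0  0  0  0999 V2000
    1.7286    0.0000    0.0000 C   0  0  0  0  0  3  0  0  0  0  0  0
    1.0777    1.3515    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.3846    1.6852    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.5574    0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.5574   -0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.3846   -1.6852    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.0777   -1.3515    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  2  0
  3  4  1  0
  4  5  2  0
  5  6  1  0
  6  7  2  0
  7  1  1  0
M  CHG  1   1   1
M  END
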
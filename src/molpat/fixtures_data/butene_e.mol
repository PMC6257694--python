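butene_e
  molpat

  4  3  0  0  0  0  0  0  0  0999 V2000
   -1.9796   -0.1365    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.5994    0.4508    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.5994   -0.4508    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.9796    0.1365    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  2  0
  3  4  1  0
M  END
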
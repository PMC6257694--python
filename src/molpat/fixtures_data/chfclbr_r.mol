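chfclbr_r
  molpat

  4  3  0  0  0  0  0  0  0  0999 V2000
   -0.0000   -0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.2990    0.7500    0.0000 F   0  0  0  0  0  0  0  0  0  0  0  0
   -1.2990    0.7500    0.0000 Cl  0  0  0  0  0  0  0  0  0  0  0  0
   -0.0000   -1.5000    0.0000 Br  0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  1
  1  3  1  0
  1  4  1  0
M  END
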
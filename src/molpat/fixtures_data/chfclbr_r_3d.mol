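chfclbr_r_3d
  molpat

  4  3  0  0  0  0  0  0  0  0999 V2000
   -0.0509   -0.1248    0.0815 C   0  0  2  0  0  0  0  0  0  0  0  0
   -0.3263   -1.1522   -0.7860 F   0  0  0  0  0  0  0  0  0  0  0  0
   -1.2453    1.1687   -0.1843 Cl  0  0  0  0  0  0  0  0  0  0  0  0
    1.6973    0.6083   -0.2417 Br  0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  6
  1  3  1  0
  1  4  1  0
M  END
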
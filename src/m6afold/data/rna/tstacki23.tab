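# m6afold table: tstacki23
# units: kcal/mol at 37 C
# pairs: CG GC GU UG AU UA
# nucleotides: A C G U
# rows: (closing pair, 5' mismatch nt); cols: 3' mismatch nt
     0      0   -0.5      0  # CG,A
     0      0      0      0  # CG,C
  -1.1      0   -0.7      0  # CG,G
     0      0      0   -0.3  # CG,U
     0      0      0      0  # GC,A
     0      0      0      0  # GC,C
  -1.2      0   -0.7      0  # GC,G
     0      0      0   -0.3  # GC,U
   0.7    0.7    0.7    0.7  # GU,A
   0.7    0.7    0.7    0.7  # GU,C
  -0.4    0.7      0    0.7  # GU,G
   0.7    0.7    0.7    0.4  # GU,U
   0.7    0.7    0.2    0.7  # UG,A
   0.7    0.7    0.7    0.7  # UG,C
  -0.4    0.7      0    0.7  # UG,G
   0.7    0.7    0.7    0.4  # UG,U
   0.7    0.7    0.7    0.7  # AU,A
   0.7    0.7    0.7    0.7  # AU,C
  -0.4    0.7      0    0.7  # AU,G
   0.7    0.7    0.7    0.4  # AU,U
   0.7    0.7    0.2    0.7  # UA,A
   0.7    0.7    0.7    0.7  # UA,C
  -0.4    0.7      0    0.7  # UA,G
   0.7    0.7    0.7    0.4  # UA,U
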
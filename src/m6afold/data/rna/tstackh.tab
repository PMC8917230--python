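# m6afold table: tstackh
# units: kcal/mol at 37 C
# pairs: CG GC GU UG AU UA
# nucleotides: A C G U
# rows: (closing pair, 5' mismatch nt); cols: 3' mismatch nt
  -1.5   -1.5   -1.4   -1.5  # CG,A
    -1   -1.1     -1   -0.8  # CG,C
  -2.3   -1.5   -2.4   -1.5  # CG,G
    -1   -1.4     -1   -2.1  # CG,U
  -1.1   -1.5   -1.3   -1.5  # GC,A
  -1.1   -0.7   -1.1   -0.5  # GC,C
  -2.5   -1.5   -2.2   -1.5  # GC,G
  -1.1     -1   -1.1   -1.6  # GC,U
   0.2   -0.5   -0.3   -0.5  # GU,A
  -0.1   -0.2   -0.1   -0.2  # GU,C
    -1   -0.5   -1.1   -0.5  # GU,G
  -0.1   -0.3   -0.1     -1  # GU,U
  -0.5   -0.3   -0.6   -0.3  # UG,A
  -0.2   -0.1   -0.2      0  # UG,C
  -0.9   -0.3   -1.1   -0.3  # UG,G
  -0.2   -0.1   -0.2   -0.9  # UG,U
  -0.3   -0.5   -0.3   -0.5  # AU,A
  -0.1   -0.2   -0.1   -0.2  # AU,C
  -1.2   -0.5   -1.1   -0.5  # AU,G
  -0.1   -0.3   -0.1   -1.2  # AU,U
  -0.5   -0.3   -0.5   -0.3  # UA,A
  -0.2   -0.1   -0.2      0  # UA,C
  -1.5   -0.3   -1.5   -0.3  # UA,G
  -0.2   -0.1   -0.2   -0.9  # UA,U
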
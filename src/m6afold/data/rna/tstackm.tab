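# m6afold table: tstackm
# units: kcal/mol at 37 C
# pairs: CG GC GU UG AU UA
# nucleotides: A C G U
# rows: (closing pair, 5' mismatch nt); cols: 3' mismatch nt
  -1.1   -1.1   -1.6   -1.1  # CG,A
  -1.5   -0.7   -1.5     -1  # CG,C
  -1.3   -1.1   -1.4   -1.1  # CG,G
  -1.5   -0.5   -1.5   -0.7  # CG,U
  -1.5     -1   -1.4     -1  # GC,A
  -1.5   -1.1   -1.5   -1.4  # GC,C
  -1.4     -1   -1.6     -1  # GC,G
  -1.5   -0.8   -1.5   -1.2  # GC,U
    -1   -0.7   -0.5   -0.7  # GU,A
  -0.8   -0.6   -0.8   -0.6  # GU,C
  -1.1   -0.7   -0.8   -0.7  # GU,G
  -0.8   -0.5   -0.8   -0.5  # GU,U
  -0.3   -0.6   -0.6   -0.6  # UG,A
    -1   -0.7     -1   -0.8  # UG,C
  -0.8   -0.6   -0.8   -0.6  # UG,G
    -1   -0.7     -1   -0.6  # UG,U
    -1   -0.7   -1.1   -0.7  # AU,A
  -0.8   -0.6   -0.8   -0.6  # AU,C
  -1.1   -0.7   -1.2   -0.7  # AU,G
  -0.8   -0.5   -0.8   -0.5  # AU,U
  -0.8   -0.6   -0.8   -0.6  # UA,A
    -1   -0.7     -1   -0.8  # UA,C
  -0.8   -0.6   -0.8   -0.6  # UA,G
    -1   -0.7     -1   -0.8  # UA,U
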
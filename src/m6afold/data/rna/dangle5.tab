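# m6afold table: dangle5
# units: kcal/mol at 37 C
# pairs: CG GC GU UG AU UA
# nucleotides: A C G U
# rows: closing pair; cols: dangling nt A C G U
  -0.5   -0.3   -0.2   -0.1  # CG
  -0.2   -0.3      0      0  # GC
  -0.3   -0.3   -0.4   -0.2  # GU
  -0.3   -0.1   -0.2   -0.2  # UG
  -0.3   -0.3   -0.4   -0.2  # AU
  -0.3   -0.1   -0.2   -0.2  # UA
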
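# m6afold table: dangle3
# units: kcal/mol at 37 C
# pairs: CG GC GU UG AU UA
# nucleotides: A C G U
# rows: closing pair; cols: dangling nt A C G U
  -1.1   -0.4   -1.3   -0.6  # CG
  -1.7   -0.8   -1.7   -1.2  # GC
  -0.7   -0.1   -0.7   -0.1  # GU
  -0.8   -0.5   -0.8   -0.6  # UG
  -0.7   -0.1   -0.7   -0.1  # AU
  -0.8   -0.5   -0.8   -0.6  # UA
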
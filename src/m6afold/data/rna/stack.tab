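# m6afold table: stack
# units: kcal/mol at 37 C
# pairs: CG GC GU UG AU UA
# nucleotides: A C G U
# rows: outer pair (i,j); cols: inner pair read (j-1,i+1)
 -2.36  -3.26   -2.1   -1.4  -2.08  -2.11  # CG
 -3.26  -3.42   -2.5   -1.5  -2.24  -2.35  # GC
  -2.1   -2.5    1.3   -0.5   -1.4   -1.3  # GU
  -1.4   -1.5   -0.5    0.3   -0.6     -1  # UG
 -2.08  -2.24   -1.4   -0.6   -1.1  -0.93  # AU
 -2.11  -2.35   -1.3     -1  -0.93  -1.33  # UA
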
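# m6afold table: int11
# units: kcal/mol at 37 C
# pairs: CG GC GU UG AU UA
# nucleotides: A C G U
# rows: (pair1, pair2, nt x on 5' side); cols: nt y on 3' side
# pair2 is the inner closing pair read (j-1-side first)
   0.9    0.5    0.5    0.5  # CG,CG,A
   0.5    0.5    0.5    0.5  # CG,CG,C
   0.5    0.5   -1.4    0.5  # CG,CG,G
   0.5    0.5    0.5    0.4  # CG,CG,U
   0.9   -0.4    0.5    0.5  # CG,GC,A
   0.3    0.5    0.5    0.6  # CG,GC,C
  -0.1    0.5   -2.2    0.5  # CG,GC,G
   0.5      0    0.5   -0.1  # CG,GC,U
   0.6    0.5    1.2    1.2  # CG,GU,A
   1.2    1.2    1.2    1.2  # CG,GU,C
  -0.2    1.2   -1.4    1.2  # CG,GU,G
   1.2      1    1.2    1.1  # CG,GU,U
   2.2    1.3    1.2    1.2  # CG,UG,A
   1.2    1.7    1.2    1.2  # CG,UG,C
   1.2    1.2   -1.4    1.2  # CG,UG,G
   1.2    1.2    1.2    1.1  # CG,UG,U
   1.2    1.2    1.2    1.2  # CG,AU,A
   1.2    1.2    1.2    1.2  # CG,AU,C
   1.2    1.2   -1.4    1.2  # CG,AU,G
   1.2    1.2    1.2    0.8  # CG,AU,U
   1.2    1.2    1.2    1.2  # CG,UA,A
   1.2    1.2    1.2    1.2  # CG,UA,C
   1.2    1.2   -1.4    1.2  # CG,UA,G
   1.2    1.2    1.2    1.2  # CG,UA,U
   0.9    0.3   -0.1    0.5  # GC,CG,A
  -0.4    0.5    0.5      0  # GC,CG,C
   0.5    0.5   -2.2    0.5  # GC,CG,G
   0.5    0.6    0.5   -0.1  # GC,CG,U
   0.8    0.5    0.5    0.5  # GC,GC,A
   0.5    0.5    0.5    0.5  # GC,GC,C
   0.5    0.5   -2.3    0.5  # GC,GC,G
   0.5    0.5    0.5   -0.6  # GC,GC,U
   1.9    1.2    1.5    1.2  # GC,GU,A
   1.2    1.2    1.2    1.2  # GC,GU,C
   1.2    1.2   -1.4    1.2  # GC,GU,G
   1.2    1.2    1.2    1.5  # GC,GU,U
   1.6    1.2      1    1.2  # GC,UG,A
   1.2    1.2    1.2    1.2  # GC,UG,C
   1.2    1.2   -1.4    1.2  # GC,UG,G
   1.2    1.2    1.2    0.7  # GC,UG,U
   1.2    1.2    1.2    1.2  # GC,AU,A
   1.2    1.2    1.2    1.2  # GC,AU,C
   1.2    1.2   -1.4    1.2  # GC,AU,G
   1.2    1.2    1.2    0.8  # GC,AU,U
   1.2    1.2    1.2    1.2  # GC,UA,A
   1.2    1.2    1.2    1.2  # GC,UA,C
   1.2    1.2   -1.4    1.2  # GC,UA,G
   1.2    1.2    1.2    1.2  # GC,UA,U
   0.6    1.2   -0.2    1.2  # GU,CG,A
   0.5    1.2    1.2      1  # GU,CG,C
   1.2    1.2   -1.4    1.2  # GU,CG,G
   1.2    1.2    1.2    1.1  # GU,CG,U
   1.9    1.2    1.2    1.2  # GU,GC,A
   1.2    1.2    1.2    1.2  # GU,GC,C
   1.5    1.2   -1.4    1.2  # GU,GC,G
   1.2    1.2    1.2    1.5  # GU,GC,U
   1.9    1.9    1.9    1.9  # GU,GU,A
   1.9    1.9    1.9    1.9  # GU,GU,C
   1.9    1.9   -0.7    1.9  # GU,GU,G
   1.9    1.9    1.9    1.2  # GU,GU,U
   1.9    1.9    1.9    1.9  # GU,UG,A
   1.9    1.9    1.9    1.9  # GU,UG,C
   1.9    1.9   -0.7    1.9  # GU,UG,G
   1.9    1.9    1.9    1.6  # GU,UG,U
   1.9    1.9    1.9    1.9  # GU,AU,A
   1.9    1.9    1.9    1.9  # GU,AU,C
   1.9    1.9   -0.7    1.9  # GU,AU,G
   1.9    1.9    1.9    1.2  # GU,AU,U
   1.9    1.9    1.9    1.9  # GU,UA,A
   1.9    1.9    1.9    1.9  # GU,UA,C
   1.9    1.9   -0.7    1.9  # GU,UA,G
   1.9    1.9    1.9    1.6  # GU,UA,U
   2.2    1.2    1.2    1.2  # UG,CG,A
   1.3    1.7    1.2    1.2  # UG,CG,C
   1.2    1.2   -1.4    1.2  # UG,CG,G
   1.2    1.2    1.2    1.1  # UG,CG,U
   1.6    1.2    1.2    1.2  # UG,GC,A
   1.2    1.2    1.2    1.2  # UG,GC,C
     1    1.2   -1.4    1.2  # UG,GC,G
   1.2    1.2    1.2    0.7  # UG,GC,U
   1.9    1.9    1.9    1.9  # UG,GU,A
   1.9    1.9    1.9    1.9  # UG,GU,C
   1.9    1.9   -0.7    1.9  # UG,GU,G
   1.9    1.9    1.9    1.6  # UG,GU,U
   1.9    1.9    1.9    1.9  # UG,UG,A
   1.9    1.9    1.9    1.9  # UG,UG,C
   1.9    1.9   -0.7    1.9  # UG,UG,G
   1.9    1.9    1.9    1.9  # UG,UG,U
   1.9    1.9    1.9    1.9  # UG,AU,A
   1.9    1.9    1.9    1.9  # UG,AU,C
   1.9    1.9   -0.7    1.9  # UG,AU,G
   1.9    1.9    1.9    1.6  # UG,AU,U
   1.9    1.9    1.9    1.9  # UG,UA,A
   1.9    1.9    1.9    1.9  # UG,UA,C
   1.9    1.9   -0.7    1.9  # UG,UA,G
   1.9    1.9    1.9    1.9  # UG,UA,U
   1.2    1.2    1.2    1.2  # AU,CG,A
   1.2    1.2    1.2    1.2  # AU,CG,C
   1.2    1.2   -1.4    1.2  # AU,CG,G
   1.2    1.2    1.2    0.8  # AU,CG,U
   1.2    1.2    1.2    1.2  # AU,GC,A
   1.2    1.2    1.2    1.2  # AU,GC,C
   1.2    1.2   -1.4    1.2  # AU,GC,G
   1.2    1.2    1.2    0.8  # AU,GC,U
   1.9    1.9    1.9    1.9  # AU,GU,A
   1.9    1.9    1.9    1.9  # AU,GU,C
   1.9    1.9   -0.7    1.9  # AU,GU,G
   1.9    1.9    1.9    1.2  # AU,GU,U
   1.9    1.9    1.9    1.9  # AU,UG,A
   1.9    1.9    1.9    1.9  # AU,UG,C
   1.9    1.9   -0.7    1.9  # AU,UG,G
   1.9    1.9    1.9    1.6  # AU,UG,U
   1.9    1.9    1.9    1.9  # AU,AU,A
   1.9    1.9    1.9    1.9  # AU,AU,C
   1.9    1.9   -0.7    1.9  # AU,AU,G
   1.9    1.9    1.9    1.2  # AU,AU,U
   1.9    1.9    1.9    1.9  # AU,UA,A
   1.9    1.9    1.9    1.9  # AU,UA,C
   1.9    1.9   -0.7    1.9  # AU,UA,G
   1.9    1.9    1.9    1.5  # AU,UA,U
   1.2    1.2    1.2    1.2  # UA,CG,A
   1.2    1.2    1.2    1.2  # UA,CG,C
   1.2    1.2   -1.4    1.2  # UA,CG,G
   1.2    1.2    1.2    1.2  # UA,CG,U
   1.2    1.2    1.2    1.2  # UA,GC,A
   1.2    1.2    1.2    1.2  # UA,GC,C
   1.2    1.2   -1.4    1.2  # UA,GC,G
   1.2    1.2    1.2    1.2  # UA,GC,U
   1.9    1.9    1.9    1.9  # UA,GU,A
   1.9    1.9    1.9    1.9  # UA,GU,C
   1.9    1.9   -0.7    1.9  # UA,GU,G
   1.9    1.9    1.9    1.6  # UA,GU,U
   1.9    1.9    1.9    1.9  # UA,UG,A
   1.9    1.9    1.9    1.9  # UA,UG,C
   1.9    1.9   -0.7    1.9  # UA,UG,G
   1.9    1.9    1.9    1.9  # UA,UG,U
   1.9    1.9    1.9    1.9  # UA,AU,A
   1.9    1.9    1.9    1.9  # UA,AU,C
   1.9    1.9   -0.7    1.9  # UA,AU,G
   1.9    1.9    1.9    1.5  # UA,AU,U
   1.9    1.9    1.9    1.9  # UA,UA,A
   1.9    1.9    1.9    1.9  # UA,UA,C
   1.9    1.9   -0.7    1.9  # UA,UA,G
   1.9    1.9    1.9    1.7  # UA,UA,U
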
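# m6afold table: special_hairpins
# units: kcal/mol at 37 C
# pairs: CG GC GU UG AU UA
# nucleotides: A C G U
# columns: loop sequence (with closing pair), kcal/mol
CAACG         6.8
GUUAC         6.9
CAACGG        5.5
CCAAGG        3.3
CCACGG        3.7
CCCAGG        3.4
CCGAGG        3.5
CCGCGG        3.6
CCUAGG        3.7
CCUCGG        2.5
CUAAGG        3.6
CUACGG        2.8
CUCAGG        3.7
CUCCGG        2.7
CUGCGG        2.8
CUUAGG        3.5
CUUCGG        3.7
CUUUGG        3.7
ACAGUACU      2.8
ACAGUGAU      3.6
ACAGUGCU      2.9
ACAGUGUU      1.8
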
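# m6afold table: loops
# units: kcal/mol at 37 C
# pairs: CG GC GU UG AU UA
# nucleotides: A C G U
# columns: n hairpin bulge internal (initiation by loop length)
  1     NA    3.8     NA
  2     NA    2.8      1
  3    5.4    3.2      1
  4    5.6    3.6    1.1
  5    5.7      4      2
  6    5.4    4.4      2
  7      6    4.6    2.1
  8    5.5    4.7    2.3
  9    6.4    4.8    2.4
 10    6.5    4.9    2.5
 11    6.6      5    2.6
 12    6.7    5.1    2.7
 13    6.8    5.2    2.8
 14    6.9    5.3    2.9
 15    6.9    5.4    2.9
 16      7    5.4      3
 17    7.1    5.5    3.1
 18    7.1    5.5    3.1
 19    7.2    5.6    3.2
 20    7.2    5.7    3.3
 21    7.3    5.7    3.3
 22    7.3    5.8    3.4
 23    7.4    5.8    3.4
 24    7.4    5.8    3.5
 25    7.5    5.9    3.5
 26    7.5    5.9    3.5
 27    7.5      6    3.6
 28    7.6      6    3.6
 29    7.6      6    3.7
 30    7.7    6.1    3.7
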
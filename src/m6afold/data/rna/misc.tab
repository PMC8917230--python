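# m6afold table: misc
# units: kcal/mol at 37 C
# pairs: CG GC GU UG AU UA
# nucleotides: A C G U
# key value
duplex_init          4.09
terminal_au          0.45
terminal_gu          0.0
terminal_gu_legacy   0.45
symmetry             0.43
ninio                0.6
ninio_max            3.0
ml_closing           9.3
ml_unpaired          0.0
ml_branch            -0.9
coax_discontinuous   -2.1
lxc                  1.07856
max_loop             30
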
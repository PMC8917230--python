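# m6afold table: measured_motifs (synthetic reference)
# Synthetic stand-ins for directly measured m6A loop motifs:
# analogous-A table values plus anchored methylation increments.
# units: kcal/mol at 37 C
# columns: kind closing-pair nts dG37 sigma
dangle3 CG 6   -1.67 0.07
dangle3 GC 6   -2.18 0.09
dangle3 AU 6   -1.06 0.05
dangle5 CG 6   -0.81 0.05
terminal_mismatch UG G6   -1.54 0.06
terminal_mismatch AU G6   -1.08 0.05
terminal_mismatch AU 66   -1.30 0.05
terminal_mismatch GC 6C   -1.35 0.05
terminal_mismatch CG 6G   -1.71 0.07
terminal_mismatch GC 6G   -1.66 0.07
terminal_mismatch UA 6C   -0.82 0.05
terminal_mismatch 6U 66   -1.72 0.07
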